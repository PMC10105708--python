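"""End-to-end phantom study: generation, segmentation, alignment,
quantification, topography, statistics and ROC diagnostics.

``run_phantom_study`` wires the stages together on a synthetic cohort:

1. generate an HC atlas cohort and a mixed HC/iPD/LRRK2 study cohort;
2. build NM and iron atlases from the HC members' annotations and score
   them with leave-one-out Dice;
3. segment every study subject per sequence, rigidly align its iron volume
   to its NM volume, and split the SN iron deposit into SNc/SNr;
4. measure CR and nVol per structure/side/sequence, fit the SNc quadrant
   frame and profile quadrants and slices;
5. run the robust group statistics and the ROC model ladder.

Every stage writes a tidy CSV into the output directory; stages are pure
functions of (inputs, config, seeds), so a rerun with the same config
reproduces every table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, quantify, robust_stats, topography
from .alignment import align_sequences, partition_sn
from .atlas import AtlasEntry, loo_quality_control, segment_target
from .image import LabelMask
from .phantom import PhantomSpec, default_signatures, generate_cohort

__all__ = ["RunConfig", "StudyResult", "run_phantom_study", "measures_wide"]


@dataclass
class RunConfig:
    out_dir: str | None = None
    seed: int = 0
    n_per_group: int = 4
    n_atlas: int = 6
    noise_sd: float = 2.0
    deform_amplitude: float = 0.5
    threshold_k: float = 2.0
    trim: float = 0.2
    n_boot_posthoc: int = 500
    n_boot_auc: int = 1000
    registration_iterations: int = 40
    run_topography: bool = True
    run_stats: bool = True
    run_roc: bool = True

    def phantom_spec(self, seed_offset: int = 0, n: int | None = None) -> PhantomSpec:
        return PhantomSpec(
            n_per_group=n if n is not None else self.n_per_group,
            noise_sd=self.noise_sd,
            deform_amplitude=self.deform_amplitude,
            rng_seed=self.seed + seed_offset,
        )


@dataclass
class StudyResult:
    config: RunConfig
    loo_qc: pd.DataFrame
    measures: pd.DataFrame
    truth: pd.DataFrame
    covariates: pd.DataFrame
    quadrant_profiles: pd.DataFrame
    asymmetry: pd.DataFrame
    group_tests: pd.DataFrame
    roc: pd.DataFrame
    alignment_qc: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _nm_entry(subject) -> AtlasEntry:
    masks = {
        (st, sd): m for (seq, st, sd), m in subject.truth_masks.items()
        if seq == "NM" and st in ("brainstem", "SNc", "LC")
    }
    return AtlasEntry(subject.subject_id, subject.nm_volume, masks)


def _iron_entry(subject) -> AtlasEntry:
    masks = {
        (st, sd): m for (seq, st, sd), m in subject.truth_masks.items()
        if seq == "iron" and st in ("brainstem", "SN", "RN")
    }
    return AtlasEntry(subject.subject_id, subject.iron_volume, masks)


def process_subject(
    subject,
    nm_atlas: list[AtlasEntry],
    iron_atlas: list[AtlasEntry],
    config: RunConfig,
) -> dict:
    """Segment, align, partition and measure one subject.

    Returns the segmentation masks, the alignment, the tidy measures and
    (optionally) the quadrant profile.
    """
    seg_nm = segment_target(
        subject.nm_volume, nm_atlas, iterations=config.registration_iterations
    )
    seg_iron = segment_target(
        subject.iron_volume, iron_atlas, iterations=config.registration_iterations
    )
    align = align_sequences(
        subject.nm_volume,
        subject.iron_volume,
        seg_nm.fused.get(("brainstem", "both")),
        seg_iron.fused.get(("brainstem", "both")),
    )
    nm_grid = subject.nm_volume
    masks: dict[tuple[str, str, str], LabelMask] = {}
    for (st, sd), m in seg_nm.fused.items():
        masks[("NM", st, sd)] = m
    # iron structures on the NM grid through the subject alignment
    from .image import apply_transform

    for (st, sd), m in seg_iron.fused.items():
        if st == "brainstem":
            continue
        on_nm = apply_transform(m, align.nm_to_iron, nm_grid, interpolation="nearest")
        masks[("iron", st, sd)] = on_nm
    for sd in ("L", "R"):
        sn_key = ("iron", "SN", sd)
        snc_key = ("NM", "SNc", sd)
        if sn_key in masks and snc_key in masks:
            snc_iron, snr = partition_sn(masks[sn_key], masks[snc_key])
            masks[("iron", "SNc", sd)] = snc_iron
            masks[("iron", "SNr", sd)] = snr
    volumes = {"NM": subject.nm_volume, "iron": align.iron_on_nm}
    brainstems = {
        "NM": masks[("NM", "brainstem", "both")],
        "iron": masks[("NM", "brainstem", "both")],
    }
    measures = quantify.measure_subject(
        volumes,
        {k: v for k, v in masks.items() if k[1] != "brainstem"},
        brainstems,
        subject.gm_volume,
        subject_id=subject.subject_id,
        group=subject.group,
        k=config.threshold_k,
    )
    profile = None
    if config.run_topography:
        snc_masks = {
            sd: masks[("NM", "SNc", sd)]
            for sd in ("L", "R")
            if ("NM", "SNc", sd) in masks and masks[("NM", "SNc", sd)].n_voxels > 10
        }
        partitions = {sd: topography.fit_quadrants(m) for sd, m in snc_masks.items()}
        if partitions:
            profile = topography.quadrant_profile(
                volumes,
                snc_masks,
                partitions,
                brainstems,
                subject.gm_volume,
                subject_id=subject.subject_id,
                group=subject.group,
                k=config.threshold_k,
            )
    return {
        "masks": masks,
        "alignment": align,
        "measures": measures,
        "profile": profile,
        "seg_qc": {"NM": seg_nm.qc, "iron": seg_iron.qc},
    }


def measure_against_truth(subject, k: float = 2.0) -> pd.DataFrame:
    """Measure a phantom subject against its own truth masks (no
    registration) and join the prescribed truths, for recovery checks."""
    volumes = {"NM": subject.nm_volume, "iron": subject.iron_volume}
    brainstems = {
        "NM": subject.truth_masks[("NM", "brainstem", "both")],
        "iron": subject.truth_masks[("iron", "brainstem", "both")],
    }
    masks = {key: m for key, m in subject.truth_masks.items() if key[1] != "brainstem"}
    measured = quantify.measure_subject(
        volumes, masks, brainstems, subject.gm_volume,
        subject_id=subject.subject_id, group=subject.group, k=k,
    ).set_index(["sequence", "structure", "side"])
    truth = subject.truth_measures.set_index(["sequence", "structure", "side"])
    return measured.join(truth[["cr_true", "nvol_true"]])


def measures_wide(measures: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot the tidy measure table into the per-subject feature table used
    by the ROC ladder (bilateral rows only)."""
    both = measures[measures["side"] == "both"].copy()
    both["feature"] = (
        both["structure"].str.lower() + "_" + both["sequence"].str.lower()
    )
    wide_cr = both.pivot_table(index=["subject_id", "group"], columns="feature",
                               values="cr", aggfunc="first")
    wide_nv = both.pivot_table(index=["subject_id", "group"], columns="feature",
                               values="nvol", aggfunc="first")
    wide = wide_cr.add_suffix("_cr").join(wide_nv.add_suffix("_nvol")).reset_index()
    if covariates is not None:
        wide = wide.merge(
            covariates[[c for c in covariates.columns if c != "group"]],
            on="subject_id",
            how="left",
        )
    return wide


def group_statistics(
    measures: pd.DataFrame,
    trim: float = 0.2,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Trimmed one-way ANOVA per headline measure, with bootstrap post hocs
    and robust effect sizes, Hochberg-adjusted within each family."""
    rows = []
    both = measures[measures["side"] == "both"]
    rng = np.random.default_rng(seed)
    for (seq, st), sub in both.groupby(["sequence", "structure"]):
        for var in ("cr", "nvol"):
            groups = sorted(sub["group"].unique())
            if len(groups) < 2:
                continue
            samples = [
                sub.loc[sub["group"] == g, var].dropna().to_numpy() for g in groups
            ]
            try:
                if len(groups) >= 3:
                    omni = robust_stats.trimmed_anova_1way(samples, trim=trim)
                else:
                    omni = robust_stats.yuen_t(samples[0], samples[1], trim=trim)
            except ValueError as exc:
                rows.append({"sequence": seq, "structure": st, "measure": var,
                             "test": "omnibus", "flags": str(exc)})
                continue
            rows.append({
                "sequence": seq, "structure": st, "measure": var,
                "test": "omnibus", "statistic": omni.statistic,
                "p": omni.p, "flags": omni.flags,
            })
            posthoc_ps = []
            posthoc_rows = []
            for a, b in combinations(range(len(groups)), 2):
                try:
                    ph = robust_stats.bootstrap_posthoc(
                        samples[a], samples[b], n_boot=n_boot, trim=trim,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    d = (
                        robust_stats.robust_cohens_d(samples[a], samples[b], trim=trim)
                        if min(len(samples[a]), len(samples[b])) >= 10
                        else np.nan
                    )
                except ValueError:
                    continue
                posthoc_ps.append(ph.p)
                posthoc_rows.append({
                    "sequence": seq, "structure": st, "measure": var,
                    "test": f"{groups[a]}_vs_{groups[b]}",
                    "statistic": ph.estimate, "p": ph.p,
                    "ci_lo": ph.ci[0], "ci_hi": ph.ci[1],
                    "effect_size": d, "flags": ph.flags,
                })
            if posthoc_ps:
                adj = robust_stats.adjust_pvalues(np.array(posthoc_ps), "hochberg")
                for r, pa in zip(posthoc_rows, adj):
                    r["p_adj"] = float(pa)
            rows.extend(posthoc_rows)
    return pd.DataFrame(rows)


def region_mixed_anova(measures: pd.DataFrame, trim: float = 0.2) -> dict:
    """Group x region (SNc vs SNr) robust mixed ANOVA of the iron measures."""
    iron = measures[
        (measures["sequence"] == "iron")
        & (measures["side"] == "both")
        & (measures["structure"].isin(["SNc", "SNr"]))
    ]
    out = {}
    for var in ("cr", "nvol"):
        data = iron.rename(columns={"structure": "within", var: "value"})[
            ["subject_id", "group", "within", "value"]
        ]
        try:
            out[var] = robust_stats.mixed_anova_2way(data, trim=trim)
        except ValueError as exc:
            out[var] = {"error": str(exc)}
    return out


def run_phantom_study(config: RunConfig) -> StudyResult:
    """Run the full pipeline on a synthetic cohort (see module docstring)."""
    # atlas cohort: healthy controls only
    atlas_spec = replace(
        config.phantom_spec(seed_offset=1000, n=config.n_atlas),
    )
    sigs = default_signatures()
    atlas_subjects, _, _ = generate_cohort(atlas_spec, {"HC": sigs["HC"]})
    nm_atlas = [_nm_entry(s) for s in atlas_subjects]
    iron_atlas = [_iron_entry(s) for s in atlas_subjects]
    loo = loo_quality_control(nm_atlas, iterations=config.registration_iterations)

    # study cohort
    spec = config.phantom_spec()
    subjects, truth, covariates = generate_cohort(spec, sigs)

    all_measures, profiles, align_rows = [], [], []
    for s in subjects:
        res = process_subject(s, nm_atlas, iron_atlas, config)
        all_measures.append(res["measures"])
        if res["profile"] is not None:
            profiles.append(res["profile"])
        align_rows.append(
            {
                "subject_id": s.subject_id,
                "brainstem_dsc": res["alignment"].qc_dice,
                "flag": res["alignment"].flagged,
            }
        )
    measures = pd.concat(all_measures, ignore_index=True)
    quadrants = (
        pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame()
    )
    asym = topography.asymmetry_table(measures)
    alignment_qc = pd.DataFrame(align_rows)

    group_tests = (
        group_statistics(
            measures, trim=config.trim, n_boot=config.n_boot_posthoc,
            seed=config.seed + 7,
        )
        if config.run_stats
        else pd.DataFrame()
    )
    extras = {}
    if config.run_stats:
        extras["region_anova"] = region_mixed_anova(measures, trim=config.trim)

    roc = pd.DataFrame()
    if config.run_roc:
        wide = measures_wide(measures, covariates)
        # tiny cohorts: in-sample logistic scores separate perfectly for
        # any feature pair, so rank models by leave-one-out AUC instead
        smallest = wide.groupby("group").size().min()
        roc = diagnostics.run_ladder(
            wide,
            n_boot=config.n_boot_auc,
            seed=config.seed + 11,
            cv="loo" if smallest < 10 else None,
        )

    result = StudyResult(
        config=config,
        loo_qc=loo,
        measures=measures,
        truth=truth,
        covariates=covariates,
        quadrant_profiles=quadrants,
        asymmetry=asym,
        group_tests=group_tests,
        roc=roc,
        alignment_qc=alignment_qc,
        extras=extras,
    )
    if config.out_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: StudyResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(result.config), indent=2))
    for name in (
        "loo_qc", "measures", "truth", "covariates", "quadrant_profiles",
        "asymmetry", "group_tests", "roc", "alignment_qc",
    ):
        df = getattr(result, name)
        if isinstance(df, pd.DataFrame) and not df.empty:
            df.to_csv(out / f"{name}.csv", index=False)
    _write_report(result, out / "report.md")


def _write_report(result: StudyResult, path: Path) -> None:
    lines = ["# Phantom study report", ""]
    lines += ["## Leave-one-out segmentation QC (Dice)", "",
              result.loo_qc.to_markdown(index=False), ""]
    both = result.measures[result.measures["side"] == "both"]
    summary = (
        both.groupby(["sequence", "structure", "group"])[["cr", "nvol"]]
        .mean()
        .reset_index()
    )
    lines += ["## Group mean measures (bilateral)", "",
              summary.to_markdown(index=False), ""]
    if not result.group_tests.empty:
        omni = result.group_tests[result.group_tests["test"] == "omnibus"]
        lines += ["## Robust group comparisons (omnibus)", "",
                  omni.to_markdown(index=False), ""]
    if not result.roc.empty:
        lines += ["## ROC ladder", "", result.roc.round(3).to_markdown(index=False), ""]
    path.write_text("\n".join(lines))
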