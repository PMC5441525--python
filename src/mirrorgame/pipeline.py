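"""End-to-end orchestration of the biomarker analysis.

``run_pipeline`` takes a cohort of recordings and produces, per feature
channel, the chain preprocess -> distribution feature -> EMD distance
matrix -> MDS embedding -> exhaustive subset search -> leave-one-out
classification result, and then fuses channels with the majority rule:

* ``solo``     — majority over the three solo channels (avatar protocol),
* ``dyad``     — majority over the two leader-follower channels,
* ``majority`` — majority over all available channels.

A channel that fails is flagged in the report and skipped by the fusion
(fusion still runs when more than one channel survives).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import mannwhitneyu

from . import distclassify, features_dyad, features_solo, preprocess
from .distclassify import ClassificationResult, majority_vote
from .synthetic_data import Cohort

logger = logging.getLogger(__name__)

SOLO_CHANNELS = ("deltaP0", "gws", "model_coeffs")
DYAD_CHANNELS = ("phase_lag_profile", "relphase_hist")


@dataclass
class RunConfig:
    """Analysis parameters of one pipeline run."""

    protocol: str = "avatar"
    feature_channels: tuple[str, ...] | None = None   # None = protocol default
    n_dims: int = 15
    max_subset_size: int = 6
    n_surrogates: int = 300
    alpha: float = 0.05
    fmax: float = 2.0
    filter_spec: preprocess.FilterSpec = field(default_factory=preprocess.FilterSpec)
    seed: int = 0

    def channels(self) -> tuple[str, ...]:
        if self.feature_channels is not None:
            return tuple(self.feature_channels)
        if self.protocol == "avatar":
            return SOLO_CHANNELS + DYAD_CHANNELS
        return DYAD_CHANNELS


@dataclass
class Report:
    channel_results: dict[str, ClassificationResult]
    fused: dict[str, ClassificationResult]
    subgroup_comparisons: dict[str, dict]
    config: RunConfig
    warnings: list[str] = field(default_factory=list)

    def rows(self) -> list[tuple[str, ClassificationResult]]:
        return list(self.channel_results.items()) + list(self.fused.items())


# --------------------------------------------------------------------------- #
# feature extraction per channel
# --------------------------------------------------------------------------- #

def _solo_features(cohort: Cohort, config: RunConfig,
                   wanted: set[str]) -> dict[str, dict[str, object]]:
    """Per-subject solo features for the requested channels."""
    out: dict[str, dict[str, object]] = {c: {} for c in wanted}
    coeffs_by_subject: dict[str, features_solo.ModelCoefficients] = {}
    for sid in cohort.subjects():
        trials = [preprocess.lowpass_filter(tr, config.filter_spec)
                  for tr in cohort.of_subject(sid, "solo")]
        if not trials:
            raise ValueError(f"subject {sid} has no solo recordings")
        if "deltaP0" in wanted:
            segs = [preprocess.extract_segments(tr) for tr in trials]
            pooled = preprocess.SegmentSet(
                signed_lengths=np.concatenate([s.signed_lengths for s in segs]),
                durations=np.concatenate([s.durations for s in segs]))
            out["deltaP0"][sid] = features_solo.deltaP0_histogram(pooled)
        if "gws" in wanted:
            out["gws"][sid] = features_solo.compute_gws(trials)
        if "model_coeffs" in wanted:
            coeffs_by_subject[sid] = features_solo.fit_motion_model(trials)
    if "model_coeffs" in wanted:
        rng_k, rng_c, scales = features_solo.cohort_coefficient_support(
            list(coeffs_by_subject.values()))
        for sid, co in coeffs_by_subject.items():
            out["model_coeffs"][sid] = features_solo.coefficient_histogram2d(
                co, rng_k, rng_c, axis_scales=scales)
    return out


def _dyad_features(cohort: Cohort, config: RunConfig,
                   wanted: set[str]) -> dict[str, dict[str, object]]:
    out: dict[str, dict[str, object]] = {c: {} for c in wanted}
    for sid in cohort.subjects():
        leaders = {tr.trial_id: tr for tr in cohort.of_subject(sid, "leader")}
        followers = {tr.trial_id: tr for tr in cohort.of_subject(sid, "follower")}
        common = sorted(set(leaders) & set(followers))
        if not common:
            raise ValueError(f"subject {sid} has no leader-follower trial pairs")
        fields = []
        for tid in common:
            lead = preprocess.lowpass_filter(leaders[tid], config.filter_spec)
            fol = preprocess.lowpass_filter(followers[tid], config.filter_spec)
            fld = features_dyad.wavelet_coherence(lead, fol)
            fld = features_dyad.significance_mask(
                fld, n_surrogates=config.n_surrogates, alpha=config.alpha,
                seed=config.seed)
            fields.append(fld)
        if "phase_lag_profile" in wanted:
            out["phase_lag_profile"][sid] = features_dyad.phase_lag_profile(fields)
        if "relphase_hist" in wanted:
            series = [features_dyad.relative_phase_series(f, fmax=config.fmax)
                      for f in fields]
            out["relphase_hist"][sid] = features_dyad.relphase_histogram(series)
    return out


def extract_features(cohort: Cohort, config: RunConfig
                     ) -> dict[str, dict[str, object]]:
    """Per-subject distribution features for every configured channel."""
    channels = set(config.channels())
    feats: dict[str, dict[str, object]] = {}
    solo_wanted = channels & set(SOLO_CHANNELS)
    dyad_wanted = channels & set(DYAD_CHANNELS)
    if solo_wanted:
        feats.update(_solo_features(cohort, config, solo_wanted))
    if dyad_wanted:
        feats.update(_dyad_features(cohort, config, dyad_wanted))
    return feats


# --------------------------------------------------------------------------- #
# pipeline
# --------------------------------------------------------------------------- #

def classify_channel(features: dict[str, object], labels: dict[str, str],
                     config: RunConfig, feature_name: str) -> dict:
    dm = distclassify.pairwise_distance_matrix(features, feature_name)
    emb = distclassify.classical_mds(dm, n_dims=config.n_dims)
    y = [labels[s] for s in emb.subject_ids]
    return distclassify.subset_search_select(
        emb, y, n_dims=config.n_dims, max_subset_size=config.max_subset_size,
        feature_name=feature_name)


def run_pipeline(config: RunConfig, cohort: Cohort) -> Report:
    """Run the full analysis on one cohort and assemble the report."""
    feats = extract_features(cohort, config)
    channel_results: dict[str, ClassificationResult] = {}
    warns: list[str] = []
    for channel in config.channels():
        try:
            sel = classify_channel(feats[channel], cohort.labels, config, channel)
            channel_results[channel] = sel["result"]
        except Exception as exc:          # noqa: BLE001 - channel isolation
            warns.append(f"channel {channel!r} failed: {exc}")
            logger.warning("channel %s failed: %s", channel, exc)

    fused: dict[str, ClassificationResult] = {}
    groupings = {
        "solo": [c for c in SOLO_CHANNELS if c in channel_results],
        "dyad": [c for c in DYAD_CHANNELS if c in channel_results],
        "majority": list(channel_results),
    }
    for name, members in groupings.items():
        if len(members) > 1:
            fused[name] = majority_vote(
                {c: channel_results[c].predictions for c in members},
                cohort.labels)
        elif name == "majority" and len(members) == 1:
            warns.append("only one channel survived; majority fusion skipped")

    comparisons = {}
    if "majority" in fused and cohort.covariates:
        comparisons = tp_fn_covariate_comparisons(fused["majority"], cohort)
    return Report(channel_results=channel_results, fused=fused,
                  subgroup_comparisons=comparisons, config=config,
                  warnings=warns)


# --------------------------------------------------------------------------- #
# subgroup comparison utility
# --------------------------------------------------------------------------- #

def compare_groups(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney-Wilcoxon U comparison of two samples.

    Uses exact enumeration for combined n <= 12 without ties and the
    tie-corrected normal approximation otherwise.  Completely tied
    inputs give p = 1 with a warning.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return {"U": len(a) * len(b) / 2.0, "p": 1.0}
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def tp_fn_covariate_comparisons(result: ClassificationResult,
                                cohort: Cohort) -> dict[str, dict]:
    """Compare correctly vs wrongly classified patients on each covariate."""
    tp = [s for s, p in result.predictions.items()
          if p == "patient" and cohort.labels[s] == "patient"]
    fn = [s for s, p in result.predictions.items()
          if p == "control" and cohort.labels[s] == "patient"]
    out: dict[str, dict] = {}
    if not tp or not fn:
        return out
    covariate_names = sorted({k for v in cohort.covariates.values() for k in v})
    for name in covariate_names:
        va = [cohort.covariates[s][name] for s in tp if name in cohort.covariates[s]]
        vb = [cohort.covariates[s][name] for s in fn if name in cohort.covariates[s]]
        if va and vb:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = compare_groups(va, vb)
    return out


# --------------------------------------------------------------------------- #
# report rendering
# --------------------------------------------------------------------------- #

def render_table(report: Report) -> str:
    """Plain-text table of confusion counts and metrics per row."""
    header = f"{'Row':<20}{'TN':>4}{'FP':>4}{'TP':>4}{'FN':>4}" \
             f"{'Accuracy':>10}{'Sens.':>8}{'Spec.':>8}{'Prec.':>8}"
    lines = [header, "-" * len(header)]
    for name, res in report.rows():
        c, m = res.counts, res.metrics
        prec = f"{m['precision']:.4f}" if np.isfinite(m["precision"]) else "nan"
        lines.append(
            f"{name:<20}{c.TN:>4}{c.FP:>4}{c.TP:>4}{c.FN:>4}"
            f"{m['accuracy']:>10.4f}{m['sensitivity']:>8.4f}"
            f"{m['specificity']:>8.4f}{prec:>8}")
    for name, cmp_res in report.subgroup_comparisons.items():
        lines.append(f"TP-vs-FN {name}: U={cmp_res['U']:.1f} p={cmp_res['p']:.4f}")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def report_to_dict(report: Report) -> dict:
    """JSON-serializable report (every metric recomputable from counts)."""
    def res_dict(res: ClassificationResult) -> dict:
        return {
            "predictions": res.predictions,
            "counts": {"TP": res.counts.TP, "FP": res.counts.FP,
                       "TN": res.counts.TN, "FN": res.counts.FN},
            "metrics": res.metrics,
            "spec": str(res.spec),
        }

    cfg = asdict(report.config)
    cfg["filter_spec"] = {"cutoff": report.config.filter_spec.cutoff,
                          "order": report.config.filter_spec.order}
    return {
        "channels": {k: res_dict(v) for k, v in report.channel_results.items()},
        "fused": {k: res_dict(v) for k, v in report.fused.items()},
        "subgroup_comparisons": report.subgroup_comparisons,
        "config": cfg,
        "warnings": report.warnings,
    }
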