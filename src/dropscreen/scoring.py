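"""Dropout-screen scoring: T0 filter, log2FC, gene dependency scores,
control QC, depletion counting, and differential (ALT vs control) calling.

The scoring chain follows the screen's published analysis rules:

* guides with a T0 read count below ``min_t0_count`` (default 50) are
  discarded per condition;
* abundance is the pseudocounted within-sample frequency, so log2FC is
  sequencing-depth invariant;
* a guide's score is ``log2FC = log2(f_Tend / f_T0)`` — depletion is
  negative, and a guide is called robustly depleted when log2FC falls
  below the depletion threshold (default -5.0);
* a gene's dependency score (GDS) is the arithmetic mean of the log2FC of
  its unfiltered guides;
* differential vulnerability compares mean GDS between the ALT and control
  condition groups; a gene is ALT-selective when it is essential in ALT
  (GDS_alt <= tau_ess) yet near-neutral in controls (GDS_ctrl >= tau_neut).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ScoringError
from .library import Library, NEGATIVE_CONTROL, POSITIVE_CONTROL, TARGETING
from .quantify import CountMatrix

ALT_SELECTIVE = "ALT-selective"
PAN_ESSENTIAL = "pan-essential"
NEITHER = "neither"


@dataclass(frozen=True)
class ScoringConfig:
    min_t0_count: int = 50
    pseudocount: float = 0.5
    depletion_threshold: float = -5.0
    doublings: int = 16
    tau_ess: float = -2.0
    tau_neut: float = -1.0

    def __post_init__(self) -> None:
        if self.min_t0_count < 0:
            raise ScoringError("min_t0_count must be >= 0")
        if self.pseudocount <= 0:
            raise ScoringError("pseudocount must be > 0")
        if self.doublings < 1:
            raise ScoringError("doublings must be >= 1")
        if not self.tau_ess < self.tau_neut:
            raise ScoringError("tau_ess must be strictly below tau_neut")


@dataclass
class FilterResult:
    """Per-condition filter flags and the discard audit list."""

    filtered: pd.DataFrame  # bool, index guide_id, one column per condition
    discards: pd.DataFrame  # guide_id, condition, t0_count


def _t0_counts(cm: CountMatrix, condition: str) -> pd.Series:
    sids = cm.samples_for(condition, "T0")
    if not sids:
        raise ScoringError(f"condition {condition!r} has no T0 sample")
    # with T0 replicates a guide must clear the filter in each of them
    return cm.counts[sids].min(axis=1)


def filter_min_t0(cm: CountMatrix, cfg: ScoringConfig) -> FilterResult:
    """Flag guides whose T0 read count is strictly below ``min_t0_count``.

    Flags are per condition; the count matrix itself is left untouched so
    the discard decisions stay auditable.
    """
    flags = {}
    rows = []
    for cond in cm.conditions:
        t0 = _t0_counts(cm, cond)
        low = t0 < cfg.min_t0_count
        flags[cond] = low
        for guide_id in t0.index[low]:
            rows.append(
                {"guide_id": guide_id, "condition": cond,
                 "t0_count": t0[guide_id]}
            )
    filtered = pd.DataFrame(flags, index=cm.counts.index)
    discards = pd.DataFrame(rows, columns=["guide_id", "condition", "t0_count"])
    return FilterResult(filtered=filtered, discards=discards)


def to_frequencies(
    cm: CountMatrix,
    cfg: ScoringConfig,
    filtered: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Pseudocounted within-sample frequencies over the retained guides.

    ``freq_i = (count_i + pc) / sum_j (count_j + pc)``, the sum running over
    guides retained in the sample's condition; filtered guides get NaN.
    Each column sums to 1 within 1e-12.
    """
    out = pd.DataFrame(index=cm.counts.index, columns=cm.sample_ids,
                       dtype=float)
    for sid in cm.sample_ids:
        col = cm.counts[sid].astype(float)
        if col.sum() == 0:
            raise ScoringError(f"sample {sid!r} has zero total counts")
        if filtered is not None:
            cond = cm.samples.loc[sid, "condition"]
            keep = ~filtered[cond]
        else:
            keep = pd.Series(True, index=col.index)
        shifted = col[keep] + cfg.pseudocount
        out.loc[keep, sid] = shifted / shifted.sum()
    return out


def guide_log2fc(t0_freq, tend_freq):
    """Elementwise ``log2(tend_freq / t0_freq)``; depletion is negative."""
    t0 = np.asarray(t0_freq, dtype=float)
    tend = np.asarray(tend_freq, dtype=float)
    if np.any(t0 <= 0) or np.any(tend <= 0):
        raise ScoringError("frequencies must be positive (pseudocount them)")
    out = np.log2(tend / t0)
    return float(out) if out.ndim == 0 else out


def score_guides(cm: CountMatrix, cfg: ScoringConfig) -> pd.DataFrame:
    """Full per-guide scoring: filter, normalize, log2FC per condition.

    Returns the guide-score table with one row per (guide, condition):
    columns guide_id, condition, t0_count, t0_freq, tend_freq, log2fc,
    filtered.  Filtered guides carry NaN scores. Conditions with several
    Tend replicates use the mean Tend frequency.
    """
    filt = filter_min_t0(cm, cfg)
    freqs = to_frequencies(cm, cfg, filt.filtered)
    rows = []
    for cond in cm.conditions:
        t0_ids = cm.samples_for(cond, "T0")
        tend_ids = cm.samples_for(cond, "Tend")
        if not tend_ids:
            raise ScoringError(f"condition {cond!r} has no Tend sample")
        t0_counts = _t0_counts(cm, cond)
        f0 = freqs[t0_ids].mean(axis=1)
        fend = freqs[tend_ids].mean(axis=1)
        flagged = filt.filtered[cond]
        lfc = pd.Series(np.nan, index=f0.index)
        keep = ~flagged
        lfc[keep] = np.log2(fend[keep] / f0[keep])
        rows.append(
            pd.DataFrame(
                {
                    "guide_id": f0.index,
                    "condition": cond,
                    "t0_count": t0_counts.to_numpy(),
                    "t0_freq": f0.to_numpy(),
                    "tend_freq": fend.to_numpy(),
                    "log2fc": lfc.to_numpy(),
                    "filtered": flagged.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gene_dependency_score(
    guide_scores: pd.DataFrame, lib: Library
) -> pd.DataFrame:
    """Per-gene dependency score: mean log2FC of the gene's unfiltered guides.

    Genes whose guides were all filtered in a condition are reported with
    ``absent=True`` and NaN GDS (never as zero, which would mimic
    neutrality).  Scored guides must exist in the library.
    """
    unknown = set(guide_scores["guide_id"]) - set(lib.guide_ids)
    if unknown:
        raise ScoringError(
            f"guide scores reference guides absent from library: "
            f"{sorted(unknown)[:5]}"
        )
    guide_gene = {
        r.guide_id: r.target
        for r in lib
        if r.category in (TARGETING, POSITIVE_CONTROL)
    }
    scores = guide_scores[guide_scores["guide_id"].isin(guide_gene)].copy()
    scores["gene"] = scores["guide_id"].map(guide_gene)
    rows = []
    for (gene, cond), grp in scores.groupby(["gene", "condition"], sort=True):
        vals = grp.loc[~grp["filtered"], "log2fc"].dropna()
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "gds": vals.mean() if len(vals) else np.nan,
                "n_guides_used": int(len(vals)),
                "absent": len(vals) == 0,
                "guide_log2fcs": list(vals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "gds", "n_guides_used", "absent",
                 "guide_log2fcs"],
    )


def count_depleted_guides(
    guide_scores: pd.DataFrame,
    lib: Library,
    threshold: float = -5.0,
    conditions: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Per gene, the number of guides with log2FC below ``threshold`` in
    every listed condition.

    A guide filtered in any of the conditions never qualifies.
    """
    if not np.isfinite(threshold):
        raise ScoringError("threshold must be finite")
    available = set(guide_scores["condition"])
    conds = list(conditions) if conditions is not None else sorted(available)
    if not conds:
        raise ScoringError("at least one condition required")
    unknown = set(conds) - available
    if unknown:
        raise ScoringError(f"unknown condition label(s): {sorted(unknown)}")
    guide_gene = {
        r.guide_id: r.target
        for r in lib
        if r.category in (TARGETING, POSITIVE_CONTROL)
    }
    sub = guide_scores[guide_scores["condition"].isin(conds)]
    sub = sub[sub["guide_id"].isin(guide_gene)]
    wide_lfc = sub.pivot(index="guide_id", columns="condition", values="log2fc")
    wide_filt = sub.pivot(index="guide_id", columns="condition",
                          values="filtered").astype(bool)
    qualifies = (wide_lfc < threshold).all(axis=1) & ~wide_filt.any(axis=1)
    genes = pd.Series({g: guide_gene[g] for g in qualifies.index})
    counts = qualifies.groupby(genes).sum().astype(int)
    all_genes = sorted(set(guide_gene.values()))
    return counts.reindex(all_genes, fill_value=0)


def differential_gds(
    gene_scores: pd.DataFrame,
    alt_conditions: Sequence[str],
    control_conditions: Sequence[str],
    cfg: ScoringConfig,
) -> pd.DataFrame:
    """Rank genes by differential dependency between condition groups.

    Per gene: ``gds_alt`` and ``gds_ctrl`` are unweighted means of the
    per-condition GDS over each group, ``delta_gds = gds_alt - gds_ctrl``.
    Classification: ALT-selective iff gds_alt <= tau_ess and gds_ctrl >=
    tau_neut; pan-essential iff both <= tau_ess; otherwise neither.
    Output is sorted by delta_gds ascending, ties broken by gds_alt then
    gene name.  Genes absent (all guides filtered) in any used condition
    are dropped and listed in ``result.attrs['dropped_genes']``.
    """
    if not list(alt_conditions) or not list(control_conditions):
        raise ScoringError("both condition groups must be non-empty")
    available = set(gene_scores["condition"])
    unknown = (set(alt_conditions) | set(control_conditions)) - available
    if unknown:
        raise ScoringError(f"unknown condition label(s): {sorted(unknown)}")
    used = list(alt_conditions) + list(control_conditions)
    sub = gene_scores[gene_scores["condition"].isin(used)]
    wide = sub.pivot(index="gene", columns="condition", values="gds")
    complete = wide[used].notna().all(axis=1)
    dropped = sorted(wide.index[~complete])
    wide = wide[complete]
    gds_alt = wide[list(alt_conditions)].mean(axis=1)
    gds_ctrl = wide[list(control_conditions)].mean(axis=1)
    delta = gds_alt - gds_ctrl
    cls = np.where(
        (gds_alt <= cfg.tau_ess) & (gds_ctrl >= cfg.tau_neut),
        ALT_SELECTIVE,
        np.where((gds_alt <= cfg.tau_ess) & (gds_ctrl <= cfg.tau_ess),
                 PAN_ESSENTIAL, NEITHER),
    )
    out = pd.DataFrame(
        {
            "gene": wide.index,
            "gds_alt": gds_alt.to_numpy(),
            "gds_ctrl": gds_ctrl.to_numpy(),
            "delta_gds": delta.to_numpy(),
            "classification": cls,
        }
    )
    out = out.sort_values(
        ["delta_gds", "gds_alt", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    out.attrs["dropped_genes"] = dropped
    return out


@dataclass
class QCReport:
    """Control-guide quality control, per condition."""

    conditions: dict = field(default_factory=dict)
    evaluable: bool = True
    message: str = ""

    @property
    def passed(self) -> bool:
        if not self.evaluable:
            return False
        return all(
            c["negatives_pass"] and c["positives_pass"]
            for c in self.conditions.values()
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "evaluable": self.evaluable,
                "message": self.message,
                "passed": self.passed if self.evaluable else None,
                "conditions": self.conditions,
            },
            sort_keys=False,
        )

    def __str__(self) -> str:
        if not self.evaluable:
            return f"QC not evaluable: {self.message}"
        lines = [f"QC {'PASS' if self.passed else 'FAIL'}"]
        for cond, c in self.conditions.items():
            lines.append(
                f"  {cond}: neg median {c['neg_median']:+.3f} "
                f"(IQR {c['neg_iqr']:.3f}) "
                f"[{'ok' if c['negatives_pass'] else 'FAIL'}]; "
                f"pos depleted {c['pos_frac_depleted']:.0%} "
                f"[{'ok' if c['positives_pass'] else 'FAIL'}]"
            )
        return "\n".join(lines)


def qc_controls(
    guide_scores: pd.DataFrame,
    lib: Library,
    cfg: ScoringConfig,
    *,
    neg_median_tol: float = 0.5,
    min_pos_depleted_frac: float = 0.5,
) -> QCReport:
    """Screen QC from the spike-in and non-targeting control guides.

    Negatives should be centred on zero (median within ``neg_median_tol``);
    positives, targeting known essential genes, should drop below the
    depletion threshold in at least ``min_pos_depleted_frac`` of guides.
    """
    negatives = set(lib.guides_by_category(NEGATIVE_CONTROL))
    positives = set(lib.guides_by_category(POSITIVE_CONTROL))
    if not negatives and not positives:
        return QCReport(evaluable=False, message="library has no control guides")
    report = QCReport()
    for cond, grp in guide_scores.groupby("condition", sort=True):
        usable = grp[~grp["filtered"]]
        neg = usable[usable["guide_id"].isin(negatives)]["log2fc"].dropna()
        pos = usable[usable["guide_id"].isin(positives)]["log2fc"].dropna()
        entry: dict = {}
        if len(neg):
            q1, med, q3 = np.percentile(neg, [25, 50, 75])
            entry["neg_median"] = float(med)
            entry["neg_iqr"] = float(q3 - q1)
            entry["n_negatives"] = int(len(neg))
            entry["negatives_pass"] = bool(abs(med) <= neg_median_tol)
        else:
            entry["neg_median"] = None
            entry["neg_iqr"] = None
            entry["n_negatives"] = 0
            entry["negatives_pass"] = False
            entry["negatives_note"] = "not evaluable"
        if len(pos):
            frac = float((pos < cfg.depletion_threshold).mean())
            entry["pos_frac_depleted"] = frac
            entry["n_positives"] = int(len(pos))
            entry["positives_pass"] = bool(frac >= min_pos_depleted_frac)
        else:
            entry["pos_frac_depleted"] = None
            entry["n_positives"] = 0
            entry["positives_pass"] = False
            entry["positives_note"] = "not evaluable"
        report.conditions[cond] = entry
    return report


def write_guide_scores_tsv(guide_scores: pd.DataFrame, path) -> None:
    guide_scores.to_csv(path, sep="\t", index=False)


def write_gene_scores_tsv(gene_scores: pd.DataFrame, path) -> None:
    out = gene_scores.drop(columns=["guide_log2fcs"])
    out.to_csv(path, sep="\t", index=False)


def write_hits_tsv(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)
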