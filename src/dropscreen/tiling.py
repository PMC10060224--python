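"""Exon-tiling scan analysis: from CDS cut sites to per-domain depletion.

A tiling library spaces guides across a single gene's coding sequence; the
growth phenotype of each knockout maps which protein regions are
functionally required.  Each guide's predicted cut position (1-based CDS
nucleotide) converts to a codon index, the codon is assigned to the unique
protein domain containing it (or ``'linker'``), and per-domain depletion is
summarized and ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ScoringError
from .library import DomainMap, Library, LibraryError, load_domain_map

LINKER = "linker"


def aa_position(cds_cut_nt: int) -> int:
    """1-based codon (amino-acid) index of a 1-based CDS nucleotide."""
    if cds_cut_nt < 1:
        raise LibraryError(f"cds_cut_nt must be >= 1, got {cds_cut_nt}")
    return (int(cds_cut_nt) - 1) // 3 + 1


def assign_domain(aa: int, dm: DomainMap) -> str:
    """Domain whose inclusive interval contains ``aa``, else ``'linker'``."""
    return dm.assign(aa)


def tile_guides(lib: Library, dm: DomainMap) -> pd.DataFrame:
    """Map every coordinate-bearing guide to its codon and domain.

    Guides lacking ``cds_cut_nt`` are excluded with a warning (a tiling
    library normally annotates all guides).
    """
    rows = []
    skipped = []
    for rec in lib:
        if rec.cds_cut_nt is None:
            skipped.append(rec.guide_id)
            continue
        aa = aa_position(rec.cds_cut_nt)
        rows.append(
            {"guide_id": rec.guide_id, "cds_cut_nt": rec.cds_cut_nt,
             "aa_position": aa, "domain": assign_domain(aa, dm)}
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} guide(s) lack cds_cut_nt and were excluded "
            f"from tiling: {skipped[:5]}",
            stacklevel=2,
        )
    if not rows:
        raise ScoringError("no guides carry cds_cut_nt coordinates")
    return pd.DataFrame(rows)


@dataclass
class TilingResult:
    """Per-guide track and per-domain summary of a tiling scan."""

    per_guide: pd.DataFrame  # guide_id, aa_position, domain, log2fc (aa order)
    per_domain: pd.DataFrame  # domain, n_guides, mean/median log2fc, rank
    condition: str


def domain_summary(
    guide_scores: pd.DataFrame,
    assignments: pd.DataFrame,
    condition: str,
    domain_map: DomainMap | None = None,
) -> TilingResult:
    """Aggregate per-guide depletion into per-domain statistics.

    Domains are ranked most-depleted-first by mean log2FC.  Domains from
    ``domain_map`` without any guide are reported with ``n_guides=0`` and
    no score.  The per-guide track is ordered by amino-acid position for
    plotting.
    """
    if condition not in set(guide_scores["condition"]):
        raise ScoringError(f"condition {condition!r} absent from guide scores")
    scores = guide_scores[guide_scores["condition"] == condition]
    merged = assignments.merge(
        scores[["guide_id", "log2fc", "filtered"]], on="guide_id", how="inner"
    )
    missing = set(assignments["guide_id"]) - set(merged["guide_id"])
    if missing:
        raise ScoringError(
            f"assigned guides missing from scores: {sorted(missing)[:5]}"
        )
    per_guide = merged.sort_values(
        ["aa_position", "guide_id"], kind="mergesort"
    ).reset_index(drop=True)
    # linear companion to the log2 score, for fold-change-style plots
    per_guide["fold_change"] = 2.0 ** per_guide["log2fc"]

    usable = per_guide[~per_guide["filtered"]]
    rows = []
    buckets = list(domain_map.names) if domain_map is not None else []
    for dom in per_guide["domain"].unique():
        if dom not in buckets:
            buckets.append(dom)
    for dom in buckets:
        vals = usable.loc[usable["domain"] == dom, "log2fc"].dropna()
        rows.append(
            {
                "domain": dom,
                "n_guides": int((per_guide["domain"] == dom).sum()),
                "mean_log2fc": vals.mean() if len(vals) else np.nan,
                "median_log2fc": vals.median() if len(vals) else np.nan,
            }
        )
    per_domain = pd.DataFrame(rows)
    per_domain["rank"] = (
        per_domain["mean_log2fc"].rank(method="min", ascending=True)
    )
    per_domain = per_domain.sort_values(
        ["rank", "domain"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return TilingResult(per_guide=per_guide, per_domain=per_domain,
                        condition=condition)


def example_domain_map() -> DomainMap:
    """The KDM2A-like domain fixture shipped with the package.

    Synthetic stand-in coordinates for a 1162-aa demethylase-family protein
    (JmjC catalytic domain, CXXC zinc finger, PHD, F-box, LRR); not measured
    annotations.
    """
    ref = resources.files("dropscreen.data") / "kdm2a_like_domains_synthetic.tsv"
    with resources.as_file(ref) as path:
        return load_domain_map(path)
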