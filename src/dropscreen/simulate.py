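"""Forward simulation of pooled CRISPR negative-selection screens.

The generative model mirrors how a dropout screen is actually run.  A
library of guides is transduced at low MOI so that every guide starts in
roughly ``cells_per_guide`` cells (with log-normal skew in the initial
representation).  The culture is then passaged for ``doublings`` population
doublings.  A cell carrying guide *i* multiplies by ``2**(1 - s_i * e_i)``
per doubling, where ``s`` is the per-gene, per-condition selection
coefficient (0 = neutral, 1 = full growth arrest relative to one extra
doubling of neutral cells) and ``e`` is the per-guide knockout efficacy.
T0 and Tend libraries are sequenced by multinomial sampling of
``seq_depth`` reads from the respective guide-frequency vectors.

The closed-form expectation of a guide's log2 fold-change under this model
(:func:`expected_log2fc`) is the analytic oracle the simulator, and every
scoring stage downstream of it, is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import SimulationError
from .library import (
    GuideRecord,
    Library,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    TARGETING,
)
from .quantify import CountMatrix, ReadLayout

#: spike-in essential genes carried as positive controls
SPIKE_IN_GENES = ("PCNA", "RPA3", "CDK1", "CDK9", "TIP60", "TTF2")
GUIDES_PER_SPIKE_IN = 5
N_TARGET_GENES = 455
N_NEGATIVE_CONTROLS = 100
NON_TARGETING = "non-targeting"

DETERMINISTIC = "deterministic"
STOCHASTIC = "stochastic"

# stage codes for per-(condition, stage) random streams; adding conditions
# or samples never perturbs the streams of earlier ones
_STAGE_INIT, _STAGE_GROWTH, _STAGE_SEQ_T0, _STAGE_SEQ_TEND = range(4)


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def expected_log2fc(
    s_eff: Union[float, np.ndarray],
    doublings: int,
    f0: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Expected log2 fold-change of a guide's frequency after ``doublings``.

    With every other cell neutral, a guide at initial frequency ``f0`` with
    effective selection ``s_eff = s * e`` reaches

        f_D = f0 * 2**g / (f0 * 2**g + (1 - f0) * 2**D),  g = (1 - s_eff) * D

    and the log2 fold-change is ``log2(f_D / f0)``.  Strictly decreasing in
    ``s_eff``; tends to ``-s_eff * D`` as ``f0 -> 0``.
    """
    s = np.asarray(s_eff, dtype=float)
    f = np.asarray(f0, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise SimulationError("s_eff must lie in [0, 1]")
    if doublings < 1:
        raise SimulationError("doublings must be >= 1")
    if np.any((f <= 0) | (f >= 1)):
        raise SimulationError("f0 must lie in the open interval (0, 1)")
    # log2(fD/f0) = g - log2(f0*2^g + (1-f0)*2^D), in log space for stability;
    # the neutral case is exactly zero, so short-circuit it past roundoff
    g = (1.0 - s) * doublings
    out = np.where(
        s == 0.0,
        0.0,
        g - np.logaddexp2(np.log2(f) + g, np.log2(1.0 - f) + doublings),
    )
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SimConfig:
    """Configuration of one simulated screen.

    ``selection`` maps condition -> gene -> selection coefficient; genes
    absent from a condition's map are neutral.  ``efficacy`` is a scalar
    applied to every guide or a per-guide mapping (default 1.0).
    ``seq_depth=0`` is the expected-count sentinel: the emitted "counts"
    are the exact frequency vectors (floats) instead of sampled reads.
    """

    library: Library
    selection: Mapping[str, Mapping[str, float]]
    efficacy: Union[float, Mapping[str, float]] = 1.0
    doublings: int = 16
    cells_per_guide: float = 1000.0
    library_skew_sigma: float = 0.3
    seq_depth: int = 10_000_000
    moi: float = 0.35  # recorded metadata; single integration assumed
    seed: int = 0
    growth_mode: str = DETERMINISTIC
    initial_frequencies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if len(self.library) == 0:
            raise SimulationError("library is empty")
        if not self.selection:
            raise SimulationError("no conditions in selection map")
        for cond, genes in self.selection.items():
            for gene, s in genes.items():
                if not 0.0 <= s <= 1.0:
                    raise SimulationError(
                        f"selection[{cond!r}][{gene!r}] = {s} outside [0, 1]"
                    )
        if self.doublings < 1:
            raise SimulationError("doublings must be >= 1")
        if self.cells_per_guide <= 0:
            raise SimulationError("cells_per_guide must be positive")
        if self.library_skew_sigma < 0:
            raise SimulationError("library_skew_sigma must be >= 0")
        if self.seq_depth < 0:
            raise SimulationError("seq_depth must be >= 0 (0 = expected mode)")
        if self.growth_mode not in (DETERMINISTIC, STOCHASTIC):
            raise SimulationError(
                f"growth_mode must be '{DETERMINISTIC}' or '{STOCHASTIC}'"
            )
        if self.initial_frequencies is not None:
            f = np.asarray(self.initial_frequencies, dtype=float)
            if f.shape != (len(self.library),):
                raise SimulationError(
                    "initial_frequencies length must equal library size"
                )
            if np.any(f <= 0):
                raise SimulationError("initial_frequencies must be positive")
            if abs(f.sum() - 1.0) > 1e-9:
                raise SimulationError("initial_frequencies must sum to 1")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.selection)

    def efficacy_vector(self) -> np.ndarray:
        if isinstance(self.efficacy, Mapping):
            e = np.array(
                [float(self.efficacy.get(g, 1.0)) for g in self.library.guide_ids]
            )
        else:
            e = np.full(len(self.library), float(self.efficacy))
        if np.any((e < 0) | (e > 1)):
            raise SimulationError("guide efficacies must lie in [0, 1]")
        return e


@dataclass
class SimResult:
    """Simulator output: counts, ground truth, and exact frequencies."""

    counts: CountMatrix
    truth: pd.DataFrame  # guide_id, gene, condition, s, e, s_eff
    frequencies: pd.DataFrame  # exact f per guide per sample (pre-sequencing)
    config: SimConfig


def simulate_counts(cfg: SimConfig) -> SimResult:
    """Run the forward model for every condition in ``cfg.selection``."""
    lib = cfg.library
    n = len(lib)
    guide_ids = lib.guide_ids
    genes = np.array([rec.target for rec in lib])
    eff = cfg.efficacy_vector()
    n_cells_total = cfg.cells_per_guide * n

    col_counts: dict[str, np.ndarray] = {}
    freq_cols: dict[str, np.ndarray] = {}
    sample_rows = []
    truth_rows = []

    for ci, cond in enumerate(cfg.conditions):
        sel = cfg.selection[cond]
        s = np.array([float(sel.get(g, 0.0)) for g in genes])
        s_eff = s * eff

        # --- initial representation ---
        if cfg.initial_frequencies is not None:
            n0 = n_cells_total * np.asarray(cfg.initial_frequencies, float)
        else:
            rng = _child_rng(cfg.seed, ci, _STAGE_INIT)
            weights = np.exp(
                rng.normal(0.0, cfg.library_skew_sigma, size=n)
            )
            p0 = weights / weights.sum()
            n0 = rng.multinomial(int(round(n_cells_total)), p0).astype(float)
            if (n0 == 0).any():
                n0 = np.maximum(n0, 1.0)  # every guide represented (MOI design)
        f0 = n0 / n0.sum()
        assert abs(f0.sum() - 1.0) < 1e-12

        # --- growth over population doublings ---
        growth = 2.0 ** ((1.0 - s_eff) * cfg.doublings)
        if cfg.growth_mode == DETERMINISTIC:
            n_end = n0 * growth
        else:
            rng_g = _child_rng(cfg.seed, ci, _STAGE_GROWTH)
            n_end = n0.copy()
            per_doubling = 2.0 ** (1.0 - s_eff)
            for _ in range(cfg.doublings):
                n_end = rng_g.poisson(n_end * per_doubling).astype(float)
        total_end = n_end.sum()
        if total_end <= 0:
            raise SimulationError(
                f"condition {cond!r}: population went extinct"
            )
        f_end = n_end / total_end
        assert abs(f_end.sum() - 1.0) < 1e-12

        # --- sequencing ---
        for tp, freqs, stage in (
            ("T0", f0, _STAGE_SEQ_T0),
            ("Tend", f_end, _STAGE_SEQ_TEND),
        ):
            sid = f"{cond}_{tp}"
            if cfg.seq_depth == 0:
                col_counts[sid] = freqs
            else:
                rng_s = _child_rng(cfg.seed, ci, stage)
                col_counts[sid] = rng_s.multinomial(cfg.seq_depth, freqs)
            freq_cols[sid] = freqs
            sample_rows.append(
                {"sample_id": sid, "timepoint": tp, "condition": cond,
                 "replicate": "1"}
            )
        truth_rows.append(
            pd.DataFrame(
                {"guide_id": guide_ids, "gene": genes, "condition": cond,
                 "s": s, "e": eff, "s_eff": s_eff}
            )
        )

    counts_df = pd.DataFrame(col_counts, index=pd.Index(guide_ids, name="guide_id"))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    cm = CountMatrix(counts=counts_df, samples=samples)
    truth = pd.concat(truth_rows, ignore_index=True)
    freqs_df = pd.DataFrame(freq_cols, index=counts_df.index)
    return SimResult(counts=cm, truth=truth, frequencies=freqs_df, config=cfg)


def emit_fastq(
    counts: CountMatrix,
    lib: Library,
    layout: ReadLayout,
    seed: int,
    out_dir,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Write one plain FASTQ per sample with exactly the tabulated reads.

    Each read is flank5 + oligo + flank3 truncated to ``read_length``,
    constant quality 'I'; substitution errors are injected at
    ``layout.error_rate``.  Requires integer counts (the expected-count
    sentinel mode cannot be rendered as reads).
    """
    import os

    missing = set(counts.guide_ids) - set(lib.guide_ids)
    if missing:
        raise SimulationError(
            f"counts contain guides absent from library: {sorted(missing)[:5]}"
        )
    max_oligo = max(lib.oligo_lengths)
    if layout.read_length < len(layout.flank5) + max_oligo:
        raise SimulationError(
            f"read_length {layout.read_length} shorter than flank5 + longest "
            f"oligo ({len(layout.flank5) + max_oligo})"
        )
    arr = counts.counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise SimulationError("emit_fastq requires integer counts")

    os.makedirs(out_dir, exist_ok=True)
    bases = np.array(list("ACGT"))
    paths: dict[str, str] = {}
    for si, sid in enumerate(counts.sample_ids):
        rng = _child_rng(seed, si, 7)
        path = os.path.join(out_dir, f"{sid}.fastq")
        col = counts.counts[sid]
        with open(path, "w", encoding="ascii") as fh:
            ridx = 0
            for guide_id in counts.guide_ids:
                n_reads = int(col[guide_id])
                if n_reads == 0:
                    continue
                rec = lib.by_id[guide_id]
                template = (layout.flank5 + rec.oligo + layout.flank3)[
                    : layout.read_length
                ]
                qual = "I" * len(template)
                if layout.error_rate == 0.0:
                    block = []
                    for _ in range(n_reads):
                        ridx += 1
                        block.append(f"@{sid}.{ridx}\n{template}\n+\n{qual}\n")
                    fh.write("".join(block))
                else:
                    L = len(template)
                    for _ in range(n_reads):
                        ridx += 1
                        n_err = rng.binomial(L, layout.error_rate)
                        seq = template
                        if n_err:
                            chars = list(seq)
                            pos = rng.choice(L, size=n_err, replace=False)
                            for p in pos:
                                alt = [b for b in bases if b != chars[p]]
                                chars[p] = alt[rng.integers(len(alt))]
                            seq = "".join(chars)
                        fh.write(f"@{sid}.{ridx}\n{seq}\n+\n{qual}\n")
        paths[sid] = path
    return paths


# ---------------------------------------------------------------------------
# library and scenario builders (the study conditions)
# ---------------------------------------------------------------------------


def _random_protospacers(rng: np.random.Generator, n: int,
                         existing: set[str], length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    taken = set(existing)
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            proto = "".join(bases[row])
            oligo = proto if proto[0] == "G" else "G" + proto
            if oligo in taken:
                continue
            taken.add(oligo)
            out.append(proto)
            if len(out) == n:
                break
    return out


def build_default_library_design(seed: int) -> Library:
    """Build a chromatin-regulator screen library like the profiled one.

    455 targeting genes with 4-14 guides each (mean ~10), 100 non-targeting
    negative controls (sgNeg1..sgNeg100) and 5 guides against each of the
    six spike-in essential genes.  Protospacers are random 20-mers with
    unique oligos.
    """
    rng = _child_rng(seed, 101)
    genes = [f"GENE{i:03d}" for i in range(1, N_TARGET_GENES + 1)]
    # 4 + Binomial(10, 0.6) has support {4..14} and mean 10
    guides_per_gene = 4 + rng.binomial(10, 0.6, size=N_TARGET_GENES)
    n_targeting = int(guides_per_gene.sum())
    n_pos = len(SPIKE_IN_GENES) * GUIDES_PER_SPIKE_IN
    n_total = n_targeting + N_NEGATIVE_CONTROLS + n_pos
    protos = _random_protospacers(rng, n_total, set())

    records: list[GuideRecord] = []
    k = 0
    for gene, n_guides in zip(genes, guides_per_gene):
        for j in range(1, int(n_guides) + 1):
            records.append(
                GuideRecord(f"sg{gene}#{j}", gene, TARGETING, protos[k])
            )
            k += 1
    for gene in SPIKE_IN_GENES:
        for j in range(1, GUIDES_PER_SPIKE_IN + 1):
            records.append(
                GuideRecord(f"sg{gene}#{j}", gene, POSITIVE_CONTROL, protos[k])
            )
            k += 1
    for i in range(1, N_NEGATIVE_CONTROLS + 1):
        records.append(
            GuideRecord(f"sgNeg{i}", NON_TARGETING, NEGATIVE_CONTROL, protos[k])
        )
        k += 1
    return Library(tuple(records), name="chromatin-regulator-design")


def screen_scenario(
    seed: int,
    *,
    library: Optional[Library] = None,
    alt_conditions: Sequence[str] = ("ALT1", "ALT2", "ALT3"),
    control_conditions: Sequence[str] = ("CTRL1", "CTRL2"),
    n_selective: int = 20,
    s_selective: float = 0.4,
    s_positive_control: float = 0.5,
    extra_selection: Optional[Mapping[str, Mapping[str, float]]] = None,
    **config_overrides,
) -> tuple[SimConfig, list[str]]:
    """Standard two-arm screen: a set of planted condition-selective genes.

    Returns the configuration and the list of planted gene names.  Planted
    genes carry ``s = s_selective`` in every ALT condition and are neutral
    in controls; spike-in positive controls are essential everywhere.
    """
    lib = library if library is not None else build_default_library_design(seed)
    rng = _child_rng(seed, 202)
    targeting_genes = sorted(
        {r.target for r in lib if r.category == TARGETING}
    )
    if n_selective > len(targeting_genes):
        raise SimulationError("more planted genes requested than genes exist")
    planted = sorted(
        rng.choice(targeting_genes, size=n_selective, replace=False).tolist()
    )
    selection: dict[str, dict[str, float]] = {}
    for cond in alt_conditions:
        sel = {g: s_selective for g in planted}
        sel.update({g: s_positive_control for g in SPIKE_IN_GENES})
        selection[cond] = sel
    for cond in control_conditions:
        selection[cond] = {g: s_positive_control for g in SPIKE_IN_GENES}
    if extra_selection:
        for cond, genes in extra_selection.items():
            selection.setdefault(cond, {}).update(genes)
    cfg = SimConfig(library=lib, selection=selection, seed=seed,
                    **config_overrides)
    return cfg, planted


def build_tiling_library(
    seed: int,
    gene: str = "KDM2A",
    n_guides: int = 120,
    cds_length_nt: int = 3486,
) -> Library:
    """Synthetic exon-tiling library: guides spread across one gene's CDS.

    Cut positions are evenly spaced with random jitter, emulating a tiling
    design over a KDM2A-sized (1162 aa) open reading frame.
    """
    rng = _child_rng(seed, 303)
    protos = _random_protospacers(rng, n_guides, set())
    spacing = cds_length_nt / n_guides
    cuts = []
    for i in range(n_guides):
        base = int(round((i + 0.5) * spacing))
        jitter = int(rng.integers(-int(spacing / 3) or 0, int(spacing / 3) + 1))
        cuts.append(int(np.clip(base + jitter, 1, cds_length_nt)))
    records = tuple(
        GuideRecord(f"sg{gene}-t{i + 1:03d}", gene, TARGETING, protos[i],
                    cds_cut_nt=cuts[i])
        for i in range(n_guides)
    )
    return Library(records, name=f"{gene}-tiling-synthetic")


def tiling_scenario(
    seed: int,
    domain_map,
    *,
    gene: str = "KDM2A",
    planted_domains: Sequence[str] = ("JmjC",),
    efficacy_in_domain: float = 0.5,
    efficacy_background: float = 0.05,
    condition: str = "ALT1",
    n_guides: int = 120,
    **config_overrides,
) -> tuple[SimConfig, Library]:
    """Tiling screen with dropout planted in selected protein domains.

    The gene is fully selected (``s = 1``) and per-guide efficacy encodes
    where knockout matters: guides cutting inside a planted domain get
    ``efficacy_in_domain``; all others ``efficacy_background``.
    """
    from .tiling import aa_position  # local import: tiling depends on library only

    lib = build_tiling_library(seed, gene=gene, n_guides=n_guides)
    eff: dict[str, float] = {}
    for rec in lib:
        aa = aa_position(rec.cds_cut_nt)
        dom = domain_map.assign(aa)
        eff[rec.guide_id] = (
            efficacy_in_domain if dom in planted_domains else efficacy_background
        )
    overrides = {"seq_depth": 1_000_000}
    overrides.update(config_overrides)
    cfg = SimConfig(
        library=lib,
        selection={condition: {gene: 1.0}},
        efficacy=eff,
        seed=seed,
        **overrides,
    )
    return cfg, lib


def write_truth_tsv(result: SimResult, path) -> None:
    result.truth.to_csv(path, sep="\t", index=False)


def config_to_dict(cfg: SimConfig) -> dict:
    """YAML-serializable mirror of a SimConfig (library by name/size only)."""
    d = {
        "library": {"name": cfg.library.name, "n_guides": len(cfg.library)},
        "selection": {c: {g: float(s) for g, s in m.items()}
                      for c, m in cfg.selection.items()},
        "efficacy": (
            {g: float(e) for g, e in cfg.efficacy.items()}
            if isinstance(cfg.efficacy, Mapping) else float(cfg.efficacy)
        ),
        "doublings": cfg.doublings,
        "cells_per_guide": cfg.cells_per_guide,
        "library_skew_sigma": cfg.library_skew_sigma,
        "seq_depth": cfg.seq_depth,
        "moi": cfg.moi,
        "seed": cfg.seed,
        "growth_mode": cfg.growth_mode,
    }
    if cfg.initial_frequencies is not None:
        d["initial_frequencies"] = [float(x) for x in cfg.initial_frequencies]
    return d
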