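"""Exact-match sgRNA quantification from FASTQ amplicon reads.

Each sequencing read is an amplicon of the integrated sgRNA cassette:
a fixed vector sequence (``flank5``), the guide oligo, and downstream
vector/scaffold sequence (``flank3``).  Counting is anchored and exact:
the 5' flank is located as an exact substring, the window that follows is
looked up in the library's oligo dictionary (trying each oligo length
present in the library, longest first), and a read increments exactly one
guide or the per-sample ``unassigned`` tally.  No mismatches are tolerated
anywhere in the oligo.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import read_tsv
from .errors import CountingError
from .library import Library

TIMEPOINTS = ("T0", "Tend", "other")

UNASSIGNED_ROW = "__unassigned__"

# Fixture amplicon structure (the real primer design is vector-specific):
# a U6-promoter tail ending just before the oligo's 5' G, and the start of
# the sgRNA scaffold downstream.
DEFAULT_FLANK5 = "TCTTGTGGAAAGGACGAAACACC"
DEFAULT_FLANK3 = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGT"


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon read structure used for both simulation and counting."""

    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    read_length: int = 75
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.flank5:
            raise CountingError("flank5 must be non-empty")
        if self.read_length < 1:
            raise CountingError("read_length must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise CountingError("error_rate must be in [0, 1)")


@dataclass
class UnassignedStats:
    """Breakdown of reads that could not be assigned to a guide."""

    no_anchor: int = 0
    too_short: int = 0
    no_match: int = 0

    @property
    def total(self) -> int:
        return self.no_anchor + self.too_short + self.no_match


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_guides(
    fastq_path,
    lib: Library,
    layout: ReadLayout,
    scan_revcomp: bool = False,
) -> tuple[pd.Series, UnassignedStats]:
    """Count exact oligo matches in one FASTQ file (plain or gzip).

    Returns a per-guide count column (library order) and the unassigned
    diagnostics.  An empty FASTQ yields a zero column with a warning; a
    malformed record raises with its record index.
    """
    oligo_map = lib.oligo_to_guide
    lengths = lib.oligo_lengths
    min_len = min(lengths)
    flank5 = layout.flank5
    k5 = len(flank5)
    counts: dict[str, int] = dict.fromkeys(lib.guide_ids, 0)
    stats = UnassignedStats()

    opener = gzip.open if str(fastq_path).endswith(".gz") else open
    n_records = 0
    with opener(fastq_path, "rt") as fh:
        iterator = FastqGeneralIterator(fh)
        while True:
            try:
                title_seq_qual = next(iterator, None)
            except ValueError as exc:
                raise CountingError(
                    f"{fastq_path}: malformed FASTQ record "
                    f"#{n_records + 1}: {exc}"
                ) from exc
            if title_seq_qual is None:
                break
            n_records += 1
            seq = title_seq_qual[1]
            guide, category = _match_read(seq, flank5, k5, oligo_map,
                                          lengths, min_len)
            if guide is None and scan_revcomp:
                rc_guide, _ = _match_read(_revcomp(seq), flank5, k5,
                                          oligo_map, lengths, min_len)
                if rc_guide is not None:
                    guide = rc_guide
            if guide is not None:
                counts[guide] += 1
            else:
                # unassigned category from the forward-strand attempt
                setattr(stats, category, getattr(stats, category) + 1)
    if n_records == 0:
        warnings.warn(f"{fastq_path}: empty FASTQ, zero counts", stacklevel=2)
    column = pd.Series(counts, name="count", dtype=np.int64)
    return column.reindex(lib.guide_ids), stats


def _match_read(seq, flank5, k5, oligo_map, lengths, min_len):
    """Return (guide_id or None, unassigned category for a miss)."""
    pos = seq.find(flank5)  # first occurrence wins (deterministic tie-break)
    if pos < 0:
        return None, "no_anchor"
    start = pos + k5
    if start + min_len > len(seq):
        return None, "too_short"
    for L in lengths:  # longest first, so a 21-mer shadows its 20-mer prefix
        window = seq[start:start + L]
        if len(window) == L:
            guide = oligo_map.get(window)
            if guide is not None:
                return guide, ""
    return None, "no_match"


@dataclass
class CountMatrix:
    """Guide-by-sample read counts plus sample metadata.

    ``counts`` is indexed by guide_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns timepoint / condition /
    replicate.  ``unassigned`` holds the per-sample unassigned-read tally.
    Counts are integers for sequenced samples; the simulator's
    expected-count mode stores float frequencies instead (documented there).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: Optional[pd.Series] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise CountingError(
                "sample metadata does not match count columns: "
                f"{list(self.counts.columns)} vs {list(self.samples.index)}"
            )
        required = {"timepoint", "condition", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise CountingError(f"sample sheet lacks columns {sorted(missing)}")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise CountingError(
                f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise CountingError("negative counts")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str, timepoint: str) -> list[str]:
        mask = (self.samples["condition"] == condition) & (
            self.samples["timepoint"] == timepoint
        )
        return list(self.samples.index[mask])


def merge_count_columns(
    columns: Mapping[str, pd.Series],
    sample_sheet: pd.DataFrame,
    guide_order: Optional[Sequence[str]] = None,
    unassigned: Optional[Mapping[str, int]] = None,
) -> CountMatrix:
    """Assemble per-sample count columns into a :class:`CountMatrix`.

    All columns must cover the identical guide universe; the sample sheet
    must describe exactly the provided sample ids.
    """
    if not columns:
        raise CountingError("no count columns supplied")
    sheet = sample_sheet.copy()
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    unknown = set(sheet.index) - set(columns)
    if unknown:
        raise CountingError(
            f"sample sheet names unknown sample_id(s): {sorted(unknown)}"
        )
    missing_meta = set(columns) - set(sheet.index)
    if missing_meta:
        raise CountingError(
            f"sample(s) missing from sample sheet: {sorted(missing_meta)}"
        )
    ids = list(columns)
    universe = set(columns[ids[0]].index)
    for sid in ids[1:]:
        other = set(columns[sid].index)
        if other != universe:
            diff = sorted(universe ^ other)
            raise CountingError(
                f"guide universe mismatch in sample {sid!r}: "
                f"differing guides {diff[:10]}"
            )
    order = list(guide_order) if guide_order is not None else list(
        columns[ids[0]].index
    )
    if set(order) != universe:
        diff = sorted(set(order) ^ universe)
        raise CountingError(f"guide order does not match universe: {diff[:10]}")
    counts = pd.DataFrame({sid: columns[sid].reindex(order) for sid in ids})
    counts.index.name = "guide_id"
    una = None
    if unassigned is not None:
        una = pd.Series({sid: int(unassigned.get(sid, 0)) for sid in ids})
    return CountMatrix(counts=counts, samples=sheet.loc[ids], unassigned=una)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    """Counts TSV: first column guide_id, one column per sample, final row
    ``__unassigned__``."""
    df = cm.counts.copy()
    if cm.unassigned is not None:
        df.loc[UNASSIGNED_ROW] = cm.unassigned.reindex(df.columns).fillna(0)
    df.index.name = "guide_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_tsv(path, dtype=str)
    missing = [
        c for c in ("sample_id", "timepoint", "condition", "replicate")
        if c not in sheet.columns
    ]
    if missing:
        raise CountingError(f"sample sheet {path} lacks columns {missing}")
    return sheet.set_index("sample_id")


def read_counts_tsv(path, sample_sheet) -> CountMatrix:
    """Load a counts TSV together with its sample sheet (path or frame)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
    except Exception as exc:  # noqa: BLE001
        raise CountingError(f"cannot parse counts TSV {path}: {exc}") from exc
    una = None
    if UNASSIGNED_ROW in df.index:
        una = df.loc[UNASSIGNED_ROW]
        df = df.drop(index=UNASSIGNED_ROW)
    if isinstance(sample_sheet, (str, bytes)) or hasattr(sample_sheet, "__fspath__"):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = sample_sheet.copy()
        if "sample_id" in sheet.columns:
            sheet = sheet.set_index("sample_id")
    sheet = sheet.loc[list(df.columns)]
    return CountMatrix(counts=df, samples=sheet, unassigned=una)
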