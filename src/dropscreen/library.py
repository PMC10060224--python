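"""sgRNA library and protein-domain data models with TSV I/O.

A pooled-screen library is a list of guides, each identified by a short
``guide_id`` and carrying the 19-20 nt protospacer that doubles as the
exact-match barcode in amplicon sequencing.  Because sgRNAs are expressed
from a U6 promoter, every oligo whose protospacer does not already begin
with G receives a prepended 5' G; the resulting ``oligo`` is the sequence
actually integrated in cells and therefore the counting reference.

Guides are either gene-targeting, non-targeting negative controls, or
spike-in positive controls against known essential genes.  Exon-tiling
libraries additionally record ``cds_cut_nt``, the 1-based nucleotide
position of the predicted Cas9 cut within the target CDS, which the tiling
module converts to an amino-acid coordinate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import cached_property
from typing import Iterator, Optional

import pandas as pd

from ._io import read_tsv
from .errors import LibraryError

DNA_ALPHABET = frozenset("ACGT")

TARGETING = "targeting"
NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
CATEGORIES = (TARGETING, NEGATIVE_CONTROL, POSITIVE_CONTROL)

#: columns a library TSV must name; ``oligo`` and ``cds_cut_nt`` are optional
REQUIRED_COLUMNS = ("guide_id", "target", "category", "protospacer")
ALL_COLUMNS = REQUIRED_COLUMNS + ("oligo", "cds_cut_nt")

MIN_GUIDES_PER_GENE = 4
MAX_GUIDES_PER_GENE = 14


def apply_5prime_g(protospacer: str) -> str:
    """Apply the U6-promoter 5' G rule to a protospacer.

    Returns ``'G' + protospacer`` when the first base is not G, otherwise
    the protospacer unchanged.  Idempotent by construction.
    """
    if not protospacer:
        raise LibraryError("protospacer is empty")
    bad = set(protospacer) - DNA_ALPHABET
    if bad:
        raise LibraryError(
            f"protospacer {protospacer!r} contains non-ACGT characters: "
            f"{sorted(bad)}"
        )
    return protospacer if protospacer[0] == "G" else "G" + protospacer


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA of a pooled library."""

    guide_id: str
    target: str
    category: str
    protospacer: str
    oligo: Optional[str] = None
    cds_cut_nt: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise LibraryError("guide_id is empty")
        if not self.target:
            raise LibraryError(f"guide {self.guide_id}: target is empty")
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"guide {self.guide_id}: unknown category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )
        if not 19 <= len(self.protospacer) <= 20:
            raise LibraryError(
                f"guide {self.guide_id}: protospacer length "
                f"{len(self.protospacer)} outside 19-20 nt"
            )
        expected = apply_5prime_g(self.protospacer)
        if self.oligo is None:
            object.__setattr__(self, "oligo", expected)
        elif self.oligo != expected:
            raise LibraryError(
                f"guide {self.guide_id}: oligo {self.oligo!r} does not equal "
                f"the protospacer after the 5' G rule ({expected!r})"
            )
        if self.cds_cut_nt is not None and self.cds_cut_nt < 1:
            raise LibraryError(
                f"guide {self.guide_id}: cds_cut_nt must be >= 1, "
                f"got {self.cds_cut_nt}"
            )


@dataclass(frozen=True)
class Library:
    """An ordered, validated collection of :class:`GuideRecord`.

    Duplicate guide ids and duplicate oligos are hard errors at
    construction: exact-match counting cannot disambiguate two guides that
    share a counting reference.
    """

    records: tuple[GuideRecord, ...]
    name: str = "library"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen_ids: dict[str, int] = {}
        seen_oligos: dict[str, str] = {}
        for rec in self.records:
            if rec.guide_id in seen_ids:
                raise LibraryError(f"duplicate guide_id {rec.guide_id!r}")
            seen_ids[rec.guide_id] = 1
            other = seen_oligos.get(rec.oligo)
            if other is not None:
                raise LibraryError(
                    f"duplicate oligo shared by guides {other!r} and "
                    f"{rec.guide_id!r}"
                )
            seen_oligos[rec.oligo] = rec.guide_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GuideRecord]:
        return iter(self.records)

    @cached_property
    def by_id(self) -> dict[str, GuideRecord]:
        return {rec.guide_id: rec for rec in self.records}

    @property
    def guide_ids(self) -> list[str]:
        return [rec.guide_id for rec in self.records]

    @cached_property
    def oligo_to_guide(self) -> dict[str, str]:
        return {rec.oligo: rec.guide_id for rec in self.records}

    @cached_property
    def oligo_lengths(self) -> tuple[int, ...]:
        """Distinct oligo lengths, longest first (counting tie-break)."""
        return tuple(sorted({len(rec.oligo) for rec in self.records},
                            reverse=True))

    @cached_property
    def gene_to_guides(self) -> dict[str, list[str]]:
        """Map gene -> guide ids, for targeting and positive-control guides."""
        out: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.category in (TARGETING, POSITIVE_CONTROL):
                out.setdefault(rec.target, []).append(rec.guide_id)
        return out

    def guides_by_category(self, category: str) -> list[str]:
        return [r.guide_id for r in self.records if r.category == category]

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(rec) for rec in self.records]
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        return df

    def write_tsv(self, path) -> None:
        """Write the canonical TSV dialect (round-trips byte-identically)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(ALL_COLUMNS) + "\n")
            for rec in self.records:
                cut = "" if rec.cds_cut_nt is None else str(rec.cds_cut_nt)
                fh.write(
                    f"{rec.guide_id}\t{rec.target}\t{rec.category}\t"
                    f"{rec.protospacer}\t{rec.oligo}\t{cut}\n"
                )

    def write_fasta(self, path) -> None:
        """Export oligos as FASTA (record id = guide_id) for external tools."""
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(f">{rec.guide_id}\n{rec.oligo}\n")


def load_library(path, name: Optional[str] = None, strict: bool = False) -> Library:
    """Load and validate a library TSV.

    The dialect is tab-separated UTF-8 with '#' comment lines and required
    columns guide_id/target/category/protospacer; ``oligo`` is computed via
    the 5' G rule when absent.  Row numbers in errors are 1-based data rows
    (comments excluded).
    """
    try:
        df = read_tsv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surfaced as a load error
        raise LibraryError(f"cannot parse library TSV {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"library TSV {path} lacks columns {missing}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        for col in REQUIRED_COLUMNS:
            val = getattr(row, col)
            if not isinstance(val, str) or not val:
                raise LibraryError(
                    f"{path}, data row {pos}: missing or empty {col!r}"
                )
        oligo = getattr(row, "oligo", None)
        if oligo is not None and pd.isna(oligo):
            oligo = None
        cut = getattr(row, "cds_cut_nt", None)
        if cut is not None and not pd.isna(cut):
            cut = int(float(cut))
        else:
            cut = None
        try:
            records.append(
                GuideRecord(
                    guide_id=row.guide_id,
                    target=row.target,
                    category=row.category,
                    protospacer=row.protospacer,
                    oligo=oligo,
                    cds_cut_nt=cut,
                )
            )
        except LibraryError as exc:
            raise LibraryError(f"{path}, data row {pos}: {exc}") from exc
    lib = Library(tuple(records), name=name or str(path))
    if strict:
        report = validate_library(lib, strict=True)
        if not report.ok:
            raise LibraryError(
                "strict validation failed:\n" + report.describe()
            )
    return lib


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    subject: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def describe(self) -> str:
        if not self.issues:
            return "library OK"
        return "\n".join(
            f"[{i.severity}] {i.subject}: {i.message}" for i in self.issues
        )


def validate_library(lib: Library, strict: bool = False) -> ValidationReport:
    """Check the per-gene guide-count design band (4-14 guides per gene).

    Control guides are exempt.  Out-of-band genes are warnings unless
    ``strict``, in which case they fail validation.  An empty library always
    fails.
    """
    issues: list[ValidationIssue] = []
    if len(lib) == 0:
        issues.append(ValidationIssue("error", lib.name, "no records"))
        return ValidationReport(tuple(issues))
    severity = "error" if strict else "warning"
    counts: dict[str, int] = {}
    for rec in lib:
        if rec.category == TARGETING:
            counts[rec.target] = counts.get(rec.target, 0) + 1
    for gene in sorted(counts):
        n = counts[gene]
        if not MIN_GUIDES_PER_GENE <= n <= MAX_GUIDES_PER_GENE:
            issues.append(
                ValidationIssue(
                    severity,
                    gene,
                    f"{n} guides outside the {MIN_GUIDES_PER_GENE}-"
                    f"{MAX_GUIDES_PER_GENE} design band",
                )
            )
    return ValidationReport(tuple(issues))


@dataclass(frozen=True)
class Domain:
    """One protein domain as a 1-based inclusive amino-acid interval."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.aa_start < 1:
            raise LibraryError(f"domain {self.name}: aa_start must be >= 1")
        if self.aa_start > self.aa_end:
            raise LibraryError(
                f"domain {self.name}: aa_start {self.aa_start} > aa_end "
                f"{self.aa_end}"
            )

    def contains(self, aa: int) -> bool:
        return self.aa_start <= aa <= self.aa_end


@dataclass(frozen=True)
class DomainMap:
    """Sorted, non-overlapping protein-domain intervals."""

    entries: tuple[Domain, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.entries, key=lambda d: d.aa_start))
        object.__setattr__(self, "entries", ordered)
        for a, b in zip(ordered, ordered[1:]):
            if b.aa_start <= a.aa_end:
                raise LibraryError(
                    f"domains {a.name!r} and {b.name!r} overlap "
                    f"({a.aa_start}-{a.aa_end} vs {b.aa_start}-{b.aa_end})"
                )

    def __iter__(self) -> Iterator[Domain]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.entries]

    def assign(self, aa: int) -> str:
        """Name of the domain containing ``aa``, else ``'linker'``."""
        for dom in self.entries:
            if dom.contains(aa):
                return dom.name
        return "linker"


def load_domain_map(path) -> DomainMap:
    """Load a domain-annotation TSV with columns name, aa_start, aa_end."""
    try:
        df = read_tsv(path)
    except Exception as exc:  # noqa: BLE001
        raise LibraryError(f"cannot parse domain TSV {path}: {exc}") from exc
    missing = [c for c in ("name", "aa_start", "aa_end") if c not in df.columns]
    if missing:
        raise LibraryError(f"domain TSV {path} lacks columns {missing}")
    entries = tuple(
        Domain(str(r.name), int(r.aa_start), int(r.aa_end))
        for r in df.itertuples(index=False)
    )
    return DomainMap(entries)


def write_domain_map(dm: DomainMap, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("name\taa_start\taa_end\n")
        for d in dm:
            fh.write(f"{d.name}\t{d.aa_start}\t{d.aa_end}\n")
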