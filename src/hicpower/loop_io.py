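"""Reading, writing, and filtering loop lists in a BEDPE dialect.

A "loop" is a focal pixel of elevated contact frequency between two distal
genomic anchors in a Hi-C map.  Records carry the observed contact counts
at the pixel and the expected counts predicted from the distance-dependent
polymer background alone, both at a stated reference sequencing depth
(total unique contacts of the source map).

Coordinates follow the BEDPE convention: 0-based, half-open intervals,
tab-separated columns ``chrom1 start1 end1 chrom2 start2 end2`` plus named
numeric columns for the counts.  Loop span is defined start-to-start on the
sorted anchors, which keeps spans a multiple of the bin size for binned
anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_MAX_SPAN = 2_000_000
DEFAULT_BIN_SIZE = 10_000
AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

#: default column layout: six BEDPE coordinates then counts
DEFAULT_DIALECT: Mapping[str, int] = {
    "chrom1": 0,
    "start1": 1,
    "end1": 2,
    "chrom2": 3,
    "start2": 4,
    "end2": 5,
    "observed": 6,
    "expected": 7,
    "name": 8,
}

_REQUIRED_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "observed", "expected",
)


class LoopParseError(ValueError):
    """Malformed row in a loop BEDPE file; message names the line number."""


def normalize_chrom(name: str) -> str:
    """Normalize chromosome naming to the ``chr``-prefixed dialect.

    Accepts both ``chr1`` and bare ``1`` styles (likewise X/Y/M/MT).
    """
    name = name.strip()
    if re.fullmatch(r"(?:[0-9]+|[XYM]|MT)", name, flags=re.IGNORECASE):
        return "chr" + name.upper().replace("MT", "M")
    return name


@dataclass(frozen=True)
class GenomicAnchor:
    """One genomic interval forming a side of a loop (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid anchor interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class LoopRecord:
    """A loop pixel: two anchors with observed/expected counts.

    ``observed`` is the Hi-C contact count recorded at the pixel and
    ``expected`` the count predicted from the polymer background at the
    same genomic separation.  ``reference_depth`` is the total unique
    contacts of the map the counts were extracted from; downstream depth
    sweeps rescale counts relative to it.
    """

    anchor1: GenomicAnchor
    anchor2: GenomicAnchor
    observed: float
    expected: float
    reference_depth: int = 0
    name: str = "."

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValueError("counts must be non-negative")

    @property
    def span(self) -> int:
        return loop_span(self)

    @property
    def intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


def loop_span(loop: LoopRecord) -> int:
    """Genomic distance between anchors, start-to-start on sorted anchors.

    Raises ``ValueError`` for inter-chromosomal loops, whose separation is
    undefined.
    """
    if loop.anchor1.chrom != loop.anchor2.chrom:
        raise ValueError(
            "span undefined for inter-chromosomal loop "
            f"({loop.anchor1.chrom} vs {loop.anchor2.chrom})"
        )
    return abs(loop.anchor2.start - loop.anchor1.start)


def bin_span(span: int, bin_size: int = DEFAULT_BIN_SIZE) -> int:
    """Bin a genomic distance to the working resolution: floor(span / bin) * bin."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if span < 0:
        raise ValueError("span must be non-negative")
    return (int(span) // int(bin_size)) * int(bin_size)


def _parse_row(
    fields: Sequence[str],
    dialect: Mapping[str, int],
    lineno: int,
    reference_depth: int,
) -> LoopRecord:
    max_idx = max(dialect[c] for c in _REQUIRED_COLUMNS)
    if len(fields) <= max_idx:
        raise LoopParseError(
            f"line {lineno}: expected at least {max_idx + 1} columns, got {len(fields)}"
        )
    try:
        start1 = int(fields[dialect["start1"]])
        end1 = int(fields[dialect["end1"]])
        start2 = int(fields[dialect["start2"]])
        end2 = int(fields[dialect["end2"]])
        observed = float(fields[dialect["observed"]])
        expected = float(fields[dialect["expected"]])
    except ValueError as exc:
        raise LoopParseError(f"line {lineno}: non-numeric field ({exc})") from None
    if not (observed == observed and expected == expected):  # NaN check
        raise LoopParseError(f"line {lineno}: missing count value")
    if observed < 0 or expected < 0:
        raise LoopParseError(f"line {lineno}: negative counts")
    a1 = GenomicAnchor(normalize_chrom(fields[dialect["chrom1"]]), start1, end1)
    a2 = GenomicAnchor(normalize_chrom(fields[dialect["chrom2"]]), start2, end2)
    # keep anchor1 upstream so span = anchor2.start - anchor1.start >= 0
    if a1.chrom == a2.chrom and a2.start < a1.start:
        a1, a2 = a2, a1
    name = "."
    if "name" in dialect and len(fields) > dialect["name"]:
        name = fields[dialect["name"]]
    try:
        return LoopRecord(a1, a2, observed, expected, reference_depth, name)
    except ValueError as exc:
        raise LoopParseError(f"line {lineno}: {exc}") from None


def read_loops(
    path: str | Path,
    dialect: Mapping[str, int] | None = None,
    reference_depth: int = 0,
) -> list[LoopRecord]:
    """Read a loop list from a BEDPE file with observed/expected columns.

    Parameters
    ----------
    path:
        Tab- (or whitespace-) separated file; lines starting with ``#`` are
        headers and skipped.
    dialect:
        Mapping of the required column names (six BEDPE coordinates plus
        ``observed`` and ``expected``) to 0-based column indices.  Defaults
        to columns 0-7 in BEDPE order.
    reference_depth:
        Total unique contacts of the source map; stamped on every record.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    missing = [c for c in _REQUIRED_COLUMNS if c not in dialect]
    if missing:
        raise ValueError(f"dialect missing required columns: {missing}")
    loops: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            loops.append(_parse_row(line.split("\t") if "\t" in line else line.split(),
                                    dialect, lineno, reference_depth))
    return loops


def write_loops(loops: Iterable[LoopRecord], path: str | Path) -> None:
    """Write loops as 8-column BEDPE (+ name) with a ``#`` header line."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tobserved\texpected\tname\n"
        )
        for lp in loops:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\t"
                f"{lp.observed!r}\t{lp.expected!r}\t{lp.name}\n"
            )


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_loops`.

    A loop failing several rules is counted once under each rule it fails,
    so the per-rule counts can exceed the total number removed.
    """

    removed_span: int = 0
    removed_chrom: int = 0
    removed_obs_le_exp: int = 0
    n_input: int = 0
    n_kept: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("span_ge_max", self.removed_span),
            ("not_autosomal", self.removed_chrom),
            ("observed_le_expected", self.removed_obs_le_exp),
        ]


def filter_loops(
    loops: Sequence[LoopRecord],
    max_span: int = DEFAULT_MAX_SPAN,
    autosomes: frozenset[str] | set[str] = AUTOSOMES,
    require_obs_gt_exp: bool = True,
) -> tuple[list[LoopRecord], FilterReport]:
    """Apply the standard loop inclusion rules.

    A loop is kept when its span is strictly shorter than ``max_span``
    (2 Mb default), both anchors lie on an autosome (chr1-chr22), and its
    observed counts strictly exceed its expected counts.  Order is
    preserved; the report counts removals per rule.
    """
    kept: list[LoopRecord] = []
    report = FilterReport(n_input=len(loops))
    for lp in loops:
        ok = True
        if lp.intra and loop_span(lp) >= max_span:
            report.removed_span += 1
            ok = False
        chroms_ok = (
            normalize_chrom(lp.anchor1.chrom) in autosomes
            and normalize_chrom(lp.anchor2.chrom) in autosomes
        )
        if not chroms_ok or not lp.intra:
            report.removed_chrom += 1
            ok = False
        if require_obs_gt_exp and not (lp.observed > lp.expected):
            report.removed_obs_le_exp += 1
            ok = False
        if ok:
            kept.append(lp)
    report.n_kept = len(kept)
    return kept, report


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rule\tremoved_count\n")
        for rule, n in report.as_rows():
            fh.write(f"{rule}\t{n}\n")
        fh.write(f"kept\t{report.n_kept}\n")
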