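"""Bidirectional-transcription origin calling from strand-specific coverage.

Active enhancers produce short divergent transcripts: in nascent-transcription
data (e.g. PRO-seq) this appears as a minus-strand read pileup just upstream
and a plus-strand pileup just downstream of the RNA polymerase II loading
site. The caller smooths each strand with a centered moving sum, locates
strand-local maxima, pairs each minus-strand maximum with its nearest
downstream plus-strand maximum, and places the origin at the mass-weighted
mean of the paired peak positions. It is a deterministic peak-pairing rule,
not a probabilistic mixture model: downstream motif-displacement analysis
needs only origin points.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: default minimum smoothed mass for a strand peak (reads)
MIN_READS = 20
#: default maximum minus-to-plus peak separation (bases)
MAX_SEPARATION = 300
#: default smoothing halfwidth (bases); window = 2*halfwidth + 1
SMOOTHING_HALFWIDTH = 30
#: default minimum distance between reported origins (bases)
MERGE_DISTANCE = 150


class BedGraphParseError(ValueError):
    """Raised on malformed bedGraph input; message carries the line number."""


@dataclass
class StrandCoverage:
    """Dense per-chromosome count arrays for the plus and minus strands.

    Minus-strand counts are stored as nonnegative magnitudes. Both strands
    share coordinates (array index = 0-based genomic position).
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.plus) != set(self.minus):
            raise ValueError("plus and minus strands must cover the same chromosomes")
        if not self.lengths:
            self.lengths = {c: len(a) for c, a in self.plus.items()}
        for chrom in self.plus:
            if len(self.plus[chrom]) != len(self.minus[chrom]):
                raise ValueError(f"{chrom}: strand arrays differ in length")
            if np.any(self.plus[chrom] < 0) or np.any(self.minus[chrom] < 0):
                raise ValueError(f"{chrom}: negative coverage values")


def read_chrom_sizes(path_or_mapping) -> dict[str, int]:
    if isinstance(path_or_mapping, Mapping):
        return dict(path_or_mapping)
    sizes = {}
    with open(path_or_mapping) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def _read_bedgraph_dense(path, sizes: dict[str, int]) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(n) for c, n in sizes.items()}
    intervals: dict[str, list[tuple[int, int, int]]] = {c: [] for c in sizes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedGraphParseError(f"{path}, line {lineno}: expected 4 fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in sizes:
                raise BedGraphParseError(f"{path}, line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= sizes[chrom]):
                raise BedGraphParseError(
                    f"{path}, line {lineno}: interval [{start}, {end}) out of bounds "
                    f"for {chrom} (length {sizes[chrom]})"
                )
            if value < 0:
                raise BedGraphParseError(f"{path}, line {lineno}: negative value {value}")
            intervals[chrom].append((start, end, lineno))
            arrays[chrom][start:end] += value
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise BedGraphParseError(
                    f"{path}, line {l2}: interval [{s2}, {e2}) overlaps line {l1}"
                )
    return arrays


def read_strand_coverage(plus_bedgraph, minus_bedgraph, chrom_sizes) -> StrandCoverage:
    """Load two bedGraph tracks (minus strand as positive magnitudes) densely."""
    sizes = read_chrom_sizes(chrom_sizes)
    return StrandCoverage(
        plus=_read_bedgraph_dense(plus_bedgraph, sizes),
        minus=_read_bedgraph_dense(minus_bedgraph, sizes),
        lengths=sizes,
    )


def write_bedgraph(array: np.ndarray, chrom: str, path, mode: str = "w") -> None:
    """Write a dense array as run-length-merged bedGraph, omitting zero runs."""
    array = np.asarray(array)
    with open(path, mode) as fh:
        if array.size == 0:
            return
        edges = np.nonzero(np.diff(array) != 0)[0] + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [array.size]))
        for s, e in zip(starts, ends):
            v = array[s]
            if v != 0:
                out = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{s}\t{e}\t{out}\n")


def write_strand_coverage(cov: StrandCoverage, plus_path, minus_path) -> None:
    for i, chrom in enumerate(sorted(cov.plus)):
        mode = "w" if i == 0 else "a"
        write_bedgraph(cov.plus[chrom], chrom, plus_path, mode)
        write_bedgraph(cov.minus[chrom], chrom, minus_path, mode)


def _smooth(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving sum with window 2*halfwidth + 1 (zero-padded ends)."""
    window = np.ones(2 * halfwidth + 1)
    return np.convolve(x, window, mode="same")


def _strand_peaks(smoothed: np.ndarray, min_reads: float):
    """Local maxima (plateau midpoints, floor) with smoothed mass >= min_reads."""
    _, props = find_peaks(smoothed, height=min_reads, plateau_size=1)
    pos = (props["left_edges"] + props["right_edges"]) // 2
    return pos.astype(int), smoothed[pos]


def call_origins(
    cov: StrandCoverage,
    min_reads: float = MIN_READS,
    max_separation: int = MAX_SEPARATION,
    smoothing_halfwidth: int = SMOOTHING_HALFWIDTH,
    merge_distance: int = MERGE_DISTANCE,
) -> pd.DataFrame:
    """Call bidirectional origins from strand-specific coverage.

    Procedure per chromosome:

    1. smooth each strand with a centered moving sum of the given halfwidth;
    2. locate strand-local maxima with smoothed mass >= *min_reads*;
    3. pair each minus-strand maximum with the nearest downstream plus-strand
       maximum when ``0 < plus_peak - minus_peak <= max_separation``;
       pairing is one-to-one, greedy by descending total smoothed mass with
       ties broken toward the smaller coordinate;
    4. origin = rounded mass-weighted mean of the paired peak positions;
    5. origins closer than *merge_distance* are merged keeping the one with
       higher total mass (ties toward the smaller coordinate).

    Returns a DataFrame with columns chrom, origin, minus_peak, plus_peak,
    minus_mass, plus_mass. An empty result is valid.
    """
    for name, v in (
        ("min_reads", min_reads),
        ("max_separation", max_separation),
        ("smoothing_halfwidth", smoothing_halfwidth),
        ("merge_distance", merge_distance),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    records = []
    for chrom in sorted(cov.plus):
        sp = _smooth(np.asarray(cov.plus[chrom], dtype=float), smoothing_halfwidth)
        sm = _smooth(np.asarray(cov.minus[chrom], dtype=float), smoothing_halfwidth)
        plus_pos, plus_mass = _strand_peaks(sp, min_reads)
        minus_pos, minus_mass = _strand_peaks(sm, min_reads)
        if plus_pos.size == 0 or minus_pos.size == 0:
            continue

        candidates = []
        for m, mm in zip(minus_pos, minus_mass):
            j = np.searchsorted(plus_pos, m + 1)  # strictly downstream
            if j < plus_pos.size and plus_pos[j] - m <= max_separation:
                candidates.append((int(m), float(mm), int(plus_pos[j]), float(sp[plus_pos[j]])))

        candidates.sort(key=lambda c: (-(c[1] + c[3]), c[0], c[2]))
        used_minus: set[int] = set()
        used_plus: set[int] = set()
        pairs = []
        for m, mm, p, pm in candidates:
            if m in used_minus or p in used_plus:
                continue
            used_minus.add(m)
            used_plus.add(p)
            origin = int(math.floor((mm * m + pm * p) / (mm + pm) + 0.5))
            pairs.append((origin, m, p, mm, pm))

        # merge: keep highest-total-mass origin in each cluster
        pairs.sort(key=lambda t: (-(t[3] + t[4]), t[0]))
        kept: list[tuple] = []
        for pair in pairs:
            if all(abs(pair[0] - k[0]) >= merge_distance for k in kept):
                kept.append(pair)
        for origin, m, p, mm, pm in kept:
            records.append((chrom, origin, m, p, mm, pm))

    df = pd.DataFrame(
        records,
        columns=["chrom", "origin", "minus_peak", "plus_peak", "minus_mass", "plus_mass"],
    )
    return df.sort_values(["chrom", "origin"], kind="stable").reset_index(drop=True)


def write_origins_bed(origins: pd.DataFrame, path) -> None:
    """Origins as BED6 1-bp intervals; name carries the strand peak masses."""
    with open(path, "w") as fh:
        for row in origins.itertuples(index=False):
            name = f"minus={row.minus_mass:.1f};plus={row.plus_mass:.1f}"
            score = int(round(row.minus_mass + row.plus_mass))
            fh.write(
                f"{row.chrom}\t{row.origin}\t{row.origin + 1}\t{name}\t{score}\t.\n"
            )


def read_origins_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name = line.split("\t")[:4]
            masses = dict(part.split("=") for part in name.split(";")) if "=" in name else {}
            rows.append(
                (
                    chrom,
                    int(start),
                    float(masses.get("minus", "nan")),
                    float(masses.get("plus", "nan")),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "origin", "minus_mass", "plus_mass"])


def write_origins_audit(origins: pd.DataFrame, path) -> None:
    origins.to_csv(path, sep="\t", index=False)
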