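"""Pol II ChIP-seq derived metrics: pausing index and peak fold change.

The promoter-proximal pausing index of a gene is the ratio of Pol II
coverage summed over the promoter window (TSS-250 to TSS+250) to the
coverage summed over the gene body (TSS+500 to TES-500), with windows
oriented by strand. Genes shorter than 1500 bp are excluded. Peak-level
condition comparison takes the maximum RPM coverage per peak in each
condition, removes peaks below 5 RPM in the control, and classifies the
remainder by the log2 fold change: below -0.1 means Pol II diminished.

Coverage is consumed as RPM-normalized per-base tracks (bedGraph or a
raw-count track converted with :meth:`CoverageTrack.to_rpm`). Window
sums of per-base coverage equal read counts up to a constant factor
under uniform read length, which cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ms2burst.stats import wilcoxon_rank_sum

PROMOTER_HALF = 250  # bp either side of the TSS
BODY_MARGIN = 500  # bp trimmed from both gene ends for the body window
MIN_GENE_LENGTH = 1500  # bp


@dataclass
class GeneRecord:
    """One gene interval (0-based, half-open) with strand-aware TSS/TES."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-chromosome per-base coverage (RPM-normalized)."""

    def __init__(self, coverage: dict[str, np.ndarray]):
        self.coverage = {c: np.asarray(v, dtype=float) for c, v in coverage.items()}
        for c, v in self.coverage.items():
            if v.size and v.min() < 0:
                raise ValueError(f"{c}: coverage must be >= 0")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.coverage

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.coverage[chrom]

    def chrom_length(self, chrom: str) -> int:
        return self.coverage[chrom].size

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, chrom_sizes: dict[str, int]
    ) -> "CoverageTrack":
        """Read a 4-column bedGraph into dense per-base arrays."""
        cov = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        for row in df.itertuples(index=False):
            if row.chrom not in cov:
                raise ValueError(f"{path}: chromosome {row.chrom!r} not in sizes file")
            n = cov[row.chrom].size
            s, e = int(row.start), int(row.end)
            if s < 0 or e > n or s >= e:
                raise ValueError(f"{path}: bad interval {row.chrom}:{s}-{e} (length {n})")
            cov[row.chrom][s:e] = float(row.value)
        return cls(cov)

    def to_bedgraph(self, path: str | Path) -> None:
        """Write nonzero runs as bedGraph lines."""
        with open(path, "w") as fh:
            for chrom in sorted(self.coverage):
                v = self.coverage[chrom]
                if v.size == 0:
                    continue
                change = np.flatnonzero(np.diff(v) != 0)
                starts = np.concatenate([[0], change + 1])
                ends = np.concatenate([change + 1, [v.size]])
                for s, e in zip(starts, ends):
                    if v[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")

    def to_rpm(self, total_reads: float) -> "CoverageTrack":
        """Scale a raw-count track to reads-per-million."""
        if total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        return CoverageTrack(
            {c: v * 1e6 / total_reads for c, v in self.coverage.items()}
        )


def read_bed6(path: str | Path) -> list[GeneRecord]:
    """Read BED6 records (name column used as the gene/peak id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return [
        GeneRecord(
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            gene_id=str(r.name),
        )
        for r in df.itertuples(index=False)
    ]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return {r.chrom: int(r.size) for r in df.itertuples(index=False)}


def _window_sum(cov: np.ndarray, start: int, end: int) -> float:
    """Sum of coverage over the half-open window, clipped to the chromosome."""
    s = max(0, start)
    e = min(cov.size, end)
    return float(cov[s:e].sum()) if e > s else 0.0


def pausing_index(
    coverage: CoverageTrack,
    genes: list[GeneRecord],
    min_gene_length: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Promoter/body coverage ratio per gene, strand-aware.

    Promoter window: [TSS-250, TSS+250); body window: [TSS+500,
    TES-500), both oriented by strand (for '-' genes the TSS is the
    interval end and the windows flip). Genes shorter than
    ``min_gene_length`` are dropped; genes with zero body signal keep a
    missing (NaN) index and are excluded from distributions.
    """
    rows = []
    for g in genes:
        if g.chrom not in coverage:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in coverage")
        n = coverage.chrom_length(g.chrom)
        if g.start < 0 or g.end > n:
            raise ValueError(
                f"gene {g.gene_id} ({g.chrom}:{g.start}-{g.end}) beyond chromosome length {n}"
            )
        if g.length < min_gene_length:
            continue
        cov = coverage[g.chrom]
        promoter = _window_sum(cov, g.tss - PROMOTER_HALF, g.tss + PROMOTER_HALF)
        # [TSS+500, TES-500) oriented by strand is [start+500, end-500) in
        # genomic coordinates for either strand
        body = _window_sum(cov, g.start + BODY_MARGIN, g.end - BODY_MARGIN)
        index = promoter / body if body > 0 else float("nan")
        rows.append((g.gene_id, promoter, body, index))
    return pd.DataFrame(
        rows, columns=["gene_id", "promoter_signal", "body_signal", "pausing_index"]
    )


def pausing_cdf(
    records_a: pd.DataFrame, records_b: pd.DataFrame, n_grid: int = 200
) -> tuple[pd.DataFrame, float]:
    """Empirical CDFs of two pausing-index sets on a shared log grid.

    Returns the CDF table (index value, F_a, F_b) and the two-sided
    rank-sum p-value between the two sets (undefined indices dropped).
    """
    a = records_a["pausing_index"].to_numpy(float)
    b = records_b["pausing_index"].to_numpy(float)
    a = np.sort(a[np.isfinite(a) & (a > 0)])
    b = np.sort(b[np.isfinite(b) & (b > 0)])
    if a.size == 0 or b.size == 0:
        raise ValueError("both pausing-index sets must be nonempty")
    lo = min(a[0], b[0])
    hi = max(a[-1], b[-1])
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    cdf = pd.DataFrame(
        {
            "pausing_index": grid,
            "cdf_a": np.searchsorted(a, grid, side="right") / a.size,
            "cdf_b": np.searchsorted(b, grid, side="right") / b.size,
        }
    )
    _, p = wilcoxon_rank_sum(a, b)
    return cdf, p


def peak_fold_change(
    cov_control: CoverageTrack,
    cov_treatment: CoverageTrack,
    peaks: list[GeneRecord],
    min_control_rpm: float = 5.0,
    diminished_cutoff: float = -0.1,
) -> pd.DataFrame:
    """Per-peak max-coverage fold change and diminished/associated call.

    A peak is filtered out when its control maximum is below
    ``min_control_rpm`` or either maximum is zero; among the rest,
    ``log2(max_treatment / max_control) < diminished_cutoff`` marks the
    peak Pol II-diminished, everything else Pol II-associated.
    """
    rows = []
    for p in peaks:
        for cov, which in ((cov_control, "control"), (cov_treatment, "treatment")):
            if p.chrom not in cov:
                raise ValueError(f"peak {p.gene_id}: chromosome {p.chrom!r} not in {which}")
            if p.start < 0 or p.end > cov.chrom_length(p.chrom):
                raise ValueError(f"peak {p.gene_id} beyond {which} chromosome bounds")
        max_a = float(cov_control[p.chrom][p.start : p.end].max())
        max_b = float(cov_treatment[p.chrom][p.start : p.end].max())
        filtered = max_a < min_control_rpm or max_a == 0.0 or max_b == 0.0
        if filtered:
            log2_fc = float("nan")
            cls = "filtered"
        else:
            log2_fc = float(np.log2(max_b / max_a))
            cls = "diminished" if log2_fc < diminished_cutoff else "associated"
        rows.append((p.chrom, p.start, p.end, p.gene_id, max_a, max_b, log2_fc, filtered, cls))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "peak_id",
            "max_control",
            "max_treatment",
            "log2_fc",
            "filtered",
            "class",
        ],
    )
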