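"""Run-of-homozygosity detection, the shared-segment catalog, and summaries.

A run is a maximal stretch of homozygous genotypes (dosage 0 or 2) within
one chromosome of one individual, spanning at least ``min_snps`` markers
(default 16: "more than 15").  Candidate shared segments are the distinct
(chromosome, start, end) intervals among all individual runs; an individual
carries a segment iff one of its own runs fully covers the segment.
Segments are kept when their carrier frequency falls inside the configured
window (default 5-95% of individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset

__all__ = [
    "HomozygousRun",
    "ROHSegment",
    "ROHCatalog",
    "detect_runs",
    "build_catalog",
    "carrier_matrix",
    "summarize_catalog",
]


@dataclass(frozen=True)
class HomozygousRun:
    sample: str
    chromosome: str
    start_idx: int  # global marker indices, inclusive
    end_idx: int
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class ROHSegment:
    chromosome: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    carriers: tuple
    n_samples: int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def carrier_frequency(self) -> float:
        return len(self.carriers) / self.n_samples


@dataclass
class ROHCatalog:
    segments: list
    runs: dict  # sample -> list[HomozygousRun]
    min_snps: int
    min_freq: float
    max_freq: float
    samples: list = field(default_factory=list)

    def __len__(self):
        return len(self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": s.chromosome,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "start_idx": s.start_idx,
                    "end_idx": s.end_idx,
                    "n_snps": s.n_snps,
                    "n_carriers": len(s.carriers),
                    "carrier_frequency": s.carrier_frequency,
                }
                for s in self.segments
            ]
        )


def _chrom_blocks(gd: GenotypeDataset):
    chrom = gd.markers["chromosome"].to_numpy()
    blocks, start = [], 0
    for j in range(1, len(chrom) + 1):
        if j == len(chrom) or chrom[j] != chrom[start]:
            blocks.append((str(chrom[start]), start, j))
            start = j
    return blocks


def detect_runs(gd: GenotypeDataset, min_snps: int = 16, max_het: int = 0) -> dict:
    """Maximal homozygous runs per sample, at least ``min_snps`` markers long.

    ``max_het`` > 0 would allow that many heterozygous calls inside a run;
    the default 0 means strictly homozygous runs.  Runs never span
    chromosome boundaries.
    """
    if gd.has_missing():
        raise ValueError("missing genotypes; impute before ROH detection")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    if max_het != 0:
        raise NotImplementedError("heterozygote-tolerant runs are not supported")
    pos = gd.markers["position_bp"].to_numpy()
    hom = gd.calls != 1
    runs = {s: [] for s in gd.samples}
    for chrom, a, b in _chrom_blocks(gd):
        block = hom[:, a:b]
        padded = np.zeros((block.shape[0], block.shape[1] + 2), dtype=bool)
        padded[:, 1:-1] = block
        d = np.diff(padded.astype(np.int8), axis=1)
        for i, sample in enumerate(gd.samples):
            starts = np.flatnonzero(d[i] == 1)
            ends = np.flatnonzero(d[i] == -1) - 1
            for s0, e0 in zip(starts, ends):
                if e0 - s0 + 1 >= min_snps:
                    gs, ge = a + s0, a + e0
                    runs[sample].append(
                        HomozygousRun(sample, chrom, gs, ge, int(pos[gs]), int(pos[ge]))
                    )
    return runs


def build_catalog(
    runs: dict,
    gd: GenotypeDataset,
    min_freq: float = 0.05,
    max_freq: float = 0.95,
    min_snps: int = 16,
) -> ROHCatalog:
    """Assemble the shared-segment catalog from per-individual runs.

    Candidate segments are the distinct intervals among all runs; the
    carrier set of a segment is every sample one of whose runs covers it
    entirely.  Segments outside [min_freq, max_freq] carrier frequency are
    dropped and exact duplicates collapsed.
    """
    if min_freq > max_freq:
        raise ValueError(f"empty frequency window: min_freq {min_freq} > max_freq {max_freq}")
    n = gd.n_samples
    by_chrom = {}
    for sample, rs in runs.items():
        for r in rs:
            by_chrom.setdefault(r.chromosome, []).append(r)
    segments = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        rs = by_chrom[chrom]
        starts = np.array([r.start_idx for r in rs])
        ends = np.array([r.end_idx for r in rs])
        samples_arr = np.array([r.sample for r in rs])
        intervals = sorted({(r.start_idx, r.end_idx) for r in rs})
        for s0, e0 in intervals:
            cover = (starts <= s0) & (ends >= e0)
            carriers = tuple(sorted(set(samples_arr[cover])))
            freq = len(carriers) / n
            if min_freq <= freq <= max_freq:
                segments.append(
                    ROHSegment(
                        chrom,
                        int(s0),
                        int(e0),
                        int(gd.markers["position_bp"].iat[s0]),
                        int(gd.markers["position_bp"].iat[e0]),
                        carriers,
                        n,
                    )
                )
    segments.sort(key=lambda s: ((len(s.chromosome), s.chromosome), s.start_idx, s.end_idx))
    return ROHCatalog(segments, runs, min_snps, min_freq, max_freq, list(gd.samples))


def carrier_matrix(catalog: ROHCatalog, gd: GenotypeDataset) -> np.ndarray:
    """Samples x segments 0/1 indicator of carrier status."""
    if list(gd.samples) != catalog.samples:
        raise ValueError("catalog was built from a dataset with different samples")
    index = {s: i for i, s in enumerate(gd.samples)}
    M = np.zeros((gd.n_samples, len(catalog.segments)), dtype=np.int8)
    for k, seg in enumerate(catalog.segments):
        for c in seg.carriers:
            M[index[c], k] = 1
    return M


def _union_length(intervals):
    """Total bp length of the union of (start, end) intervals, end-start terms."""
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_catalog(runs: dict, gd: GenotypeDataset) -> dict:
    """Descriptive run statistics and per-sample genome coverage.

    Coverage divides the union length of a sample's runs by the mapped
    autosome length (last minus first marker position, summed over
    chromosomes) — reproducible from the marker map alone.
    """
    pos = gd.markers["position_bp"].to_numpy()
    mapped = sum(int(pos[b - 1] - pos[a]) for _, a, b in _chrom_blocks(gd))
    all_runs = [r for rs in runs.values() for r in rs]
    n_snps = np.array([r.n_snps for r in all_runs])
    length = np.array([r.length_bp for r in all_runs])
    coverage = {}
    for sample in gd.samples:
        by_chrom = {}
        for r in runs.get(sample, []):
            by_chrom.setdefault(r.chromosome, []).append((r.start_bp, r.end_bp))
        union = sum(_union_length(v) for v in by_chrom.values())
        coverage[sample] = 100.0 * union / mapped if mapped else 0.0
    cov = np.array(list(coverage.values()))
    summary = {
        "n_runs": len(all_runs),
        "mapped_length_bp": mapped,
        "coverage_percent": coverage,
        "coverage_mean": float(cov.mean()) if cov.size else 0.0,
        "coverage_sd": float(cov.std(ddof=1)) if cov.size > 1 else 0.0,
    }
    if all_runs:
        summary.update(
            n_snps_min=int(n_snps.min()),
            n_snps_max=int(n_snps.max()),
            n_snps_mean=float(n_snps.mean()),
            n_snps_sd=float(n_snps.std(ddof=1)) if n_snps.size > 1 else 0.0,
            length_bp_min=int(length.min()),
            length_bp_max=int(length.max()),
            length_bp_mean=float(length.mean()),
            length_bp_sd=float(length.std(ddof=1)) if length.size > 1 else 0.0,
            hist_n_snps=pd.Series(n_snps).value_counts().sort_index().to_dict(),
        )
    else:
        summary.update(
            n_snps_min=0, n_snps_max=0, n_snps_mean=0.0, n_snps_sd=0.0,
            length_bp_min=0, length_bp_max=0, length_bp_mean=0.0, length_bp_sd=0.0,
            hist_n_snps={},
        )
    return summary
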