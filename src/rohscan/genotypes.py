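"""Genotype, pedigree and phenotype containers with PLINK text/binary I/O.

Genotypes are stored as counted-allele dosages in an ``int8`` matrix
(samples x markers) with ``-1`` marking missing calls.  For the text
dialect (.ped/.map) the counted allele of each marker is the
lexicographically smaller of the observed allele labels; for the binary
dialect (.bed/.bim/.fam) it is the A1 allele of the .bim file.  Both
conventions only flip dosage 0 <-> 2, so heterozygosity and ROH calls are
coding-invariant.

Coordinates are 1-based and inclusive, as in .map/.bim files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

__all__ = [
    "GenotypeDataset",
    "Pedigree",
    "PhenotypeTable",
    "read_plink",
    "write_plink",
    "read_pedigree",
    "read_phenotypes",
    "qc_filter",
    "impute_mode",
    "heterozygosity_percent",
]


class FormatError(ValueError):
    """Raised for malformed genotype files."""


@dataclass
class GenotypeDataset:
    """Coded SNP matrix plus marker map and sample ids.

    Attributes
    ----------
    samples : list of str
        Ordered sample ids.
    markers : pandas.DataFrame
        Columns ``marker_id``, ``chromosome``, ``position_bp``; one row per
        marker, in matrix column order.  Positions are strictly increasing
        within a chromosome.
    calls : numpy.ndarray of int8, shape (n_samples, n_markers)
        Counted-allele dosages in {0, 1, 2}; -1 is missing.
    provenance : list of str
        Human-readable notes of filters applied.
    """

    samples: list
    markers: pd.DataFrame
    calls: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()]
            raise ValueError(f"duplicate marker ids: {list(dup[:5])}")
        for _, sub in self.markers.groupby("chromosome", sort=False):
            pos = sub["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions not strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def chromosomes(self) -> list:
        seen = dict.fromkeys(self.markers["chromosome"])
        return list(seen)

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            list(self.samples),
            self.markers.copy().reset_index(drop=True),
            self.calls.copy(),
            list(self.provenance),
        )


class Pedigree:
    """Ordered (individual, sire, dam) triples; unknown parents are None.

    The constructor topologically sorts the pedigree (parents before
    offspring) and rejects cycles.
    """

    def __init__(self, triples):
        triples = [(str(i), None if not s or str(s) == "0" else str(s),
                    None if not d or str(d) == "0" else str(d))
                   for i, s, d in triples]
        ids = [t[0] for t in triples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for i, s, d in triples:
            for par in (s, d):
                if par is not None and par not in known:
                    raise ValueError(f"parent {par} of {i} not in pedigree")
        self.triples = self._toposort(triples)
        self.ids = [t[0] for t in self.triples]
        self.index = {ind: k for k, ind in enumerate(self.ids)}
        self.sire = [None if t[1] is None else self.index[t[1]] for t in self.triples]
        self.dam = [None if t[2] is None else self.index[t[2]] for t in self.triples]

    @staticmethod
    def _toposort(triples):
        parents = {i: [p for p in (s, d) if p is not None] for i, s, d in triples}
        order, state = [], {}
        by_id = {t[0]: t for t in triples}

        def visit(node, chain):
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                cyc = chain[chain.index(node):] + [node]
                raise ValueError(f"pedigree cycle: {' -> '.join(cyc)}")
            state[node] = 1
            for p in parents[node]:
                visit(p, chain + [node])
            state[node] = 2
            order.append(by_id[node])

        for i in by_id:
            visit(i, [])
        return order

    def __len__(self):
        return len(self.ids)

    def founders(self):
        return [i for i, s, d in self.triples if s is None and d is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [t[1] or "0" for t in self.triples],
                "dam": [t[2] or "0" for t in self.triples],
            }
        )

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


PARITY_CLASSES = (1, 2, 3, 4, 5)  # class 5 means parity >= 5


class PhenotypeTable:
    """Repeated litter-size records.

    Columns: ``sow`` (id), ``parity`` (class in {1,2,3,4,5}, 5 = fifth and
    beyond), ``hys`` (herd-year-season level), ``tnb`` and ``nba`` (piglets).
    """

    COLUMNS = ("sow", "parity", "hys", "tnb", "nba")

    def __init__(self, records: pd.DataFrame):
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        df = records.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        df["sow"] = df["sow"].astype(str)
        df["parity"] = df["parity"].astype(int)
        if not df["parity"].isin(PARITY_CLASSES).all():
            bad = sorted(set(df["parity"]) - set(PARITY_CLASSES))
            raise ValueError(f"invalid parity classes: {bad}")
        if (df["nba"] > df["tnb"]).any():
            raise ValueError("NBA exceeds TNB in some records")
        self.records = df

    def __len__(self):
        return len(self.records)

    @property
    def sows(self):
        return list(dict.fromkeys(self.records["sow"]))

    def trait(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in ("tnb", "nba"):
            raise ValueError(f"unknown trait {name!r}; expected TNB or NBA")
        return self.records[name].to_numpy(dtype=float)

    def write_tsv(self, path):
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK I/O
# ---------------------------------------------------------------------------

def _read_map(path):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], int(parts[3])))
    df = pd.DataFrame(rows, columns=["chromosome", "marker_id", "position_bp"])
    return df[["marker_id", "chromosome", "position_bp"]]


def _sort_markers(markers: pd.DataFrame):
    """Return (sorted markers, order) sorting by chromosome then position."""
    def chrom_key(c):
        try:
            return (0, int(c), "")
        except (TypeError, ValueError):
            return (1, 0, str(c))

    keys = [(chrom_key(c), p) for c, p in zip(markers["chromosome"], markers["position_bp"])]
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__))
    if np.array_equal(order, np.arange(len(keys))):
        return markers, None
    warnings.warn("marker map was not sorted by chromosome/position; sorting")
    return markers.iloc[order].reset_index(drop=True), order


def read_plink(path_prefix, dialect: str = "text") -> GenotypeDataset:
    """Read a PLINK fileset (``.ped/.map`` or ``.bed/.bim/.fam``).

    Dosages count the A1 allele (binary dialect) or the lexicographically
    smaller allele label (text dialect); missing calls are preserved as -1.
    """
    path_prefix = str(path_prefix)
    if dialect == "text":
        return _read_plink_text(path_prefix)
    if dialect == "binary":
        return _read_plink_binary(path_prefix)
    raise ValueError(f"unknown PLINK dialect {dialect!r}")


def _read_plink_text(prefix):
    markers = _read_map(prefix + ".map")
    samples, allele_rows = [], []
    m = len(markers)
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * m} fields for "
                    f"{m} markers, got {len(parts)}"
                )
            samples.append(parts[1])
            allele_rows.append(parts[6:])
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample ids in .ped")
    alleles = np.array(allele_rows, dtype="U8").reshape(len(samples), m, 2)
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        obs = np.unique(col[col != "0"])
        if obs.size > 2:
            raise FormatError(f"marker {markers['marker_id'][j]}: >2 alleles {list(obs)}")
        counted = min(obs) if obs.size else None
        if counted is None:
            continue
        valid = (col != "0").all(axis=1)
        calls[valid, j] = (col[valid] == counted).sum(axis=1)
    markers, order = _sort_markers(markers)
    if order is not None:
        calls = calls[:, order]
    return GenotypeDataset(samples, markers, calls, [f"read_plink text {prefix}"])


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit .bed codes -> dosage of A1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def _read_plink_binary(prefix):
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    samples = list(fam[1])
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    markers = pd.DataFrame(
        {
            "marker_id": bim[1],
            "chromosome": bim[0],
            "position_bp": bim[3].astype(int),
        }
    )
    n, m = len(samples), len(markers)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic bytes {magic!r} (expect SNP-major v1)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    stride = (n + 3) // 4
    if data.size != stride * m:
        raise FormatError(
            f"{prefix}.bed: {data.size} data bytes, expected {stride * m} "
            f"for {n} samples x {m} markers"
        )
    data = data.reshape(m, stride)
    # unpack 2-bit fields, sample-within-byte little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 3
    codes = codes.reshape(m, stride * 4)[:, :n]
    calls = _BED_DECODE[codes].T.copy()
    markers, order = _sort_markers(markers)
    if order is not None:
        calls = calls[:, order]
    return GenotypeDataset(samples, markers, calls, [f"read_plink binary {prefix}"])


def write_plink(gd: GenotypeDataset, path_prefix, dialect: str = "text"):
    """Write ``gd`` as a PLINK fileset; alleles are labelled '1' (counted)
    and '2', so text round trips preserve the dosage coding.

    One caveat is inherent to the text dialect: a marker where the counted
    allele never occurs (every dosage 0) reads back reflected (dosage 2),
    because .ped files carry no allele reference.  Heterozygosity, ROH
    calls and the G matrix are invariant to that reflection; the binary
    dialect round-trips exactly.
    """
    path_prefix = str(path_prefix)
    mk = gd.markers
    if dialect == "text":
        with open(path_prefix + ".map", "w") as fh:
            for _, r in mk.iterrows():
                fh.write(f"{r.chromosome}\t{r.marker_id}\t0\t{r.position_bp}\n")
        tokens = {2: "1 1", 1: "1 2", 0: "2 2", -1: "0 0"}
        with open(path_prefix + ".ped", "w") as fh:
            for i, s in enumerate(gd.samples):
                geno = " ".join(tokens[int(c)] for c in gd.calls[i])
                fh.write(f"{s} {s} 0 0 0 -9 {geno}\n")
    elif dialect == "binary":
        with open(path_prefix + ".fam", "w") as fh:
            for s in gd.samples:
                fh.write(f"{s} {s} 0 0 0 -9\n")
        with open(path_prefix + ".bim", "w") as fh:
            for _, r in mk.iterrows():
                fh.write(f"{r.chromosome}\t{r.marker_id}\t0\t{r.position_bp}\t1\t2\n")
        n = gd.n_samples
        stride = (n + 3) // 4
        with open(path_prefix + ".bed", "wb") as fh:
            fh.write(_BED_MAGIC)
            buf = np.zeros((gd.n_markers, stride), dtype=np.uint8)
            codes = np.array(
                [[_BED_ENCODE[int(c)] for c in gd.calls[:, j]] for j in range(gd.n_markers)],
                dtype=np.uint8,
            ).reshape(gd.n_markers, n)
            pad = np.ones((gd.n_markers, stride * 4 - n), dtype=np.uint8)  # 01 = missing pad
            codes = np.hstack([codes, pad]).reshape(gd.n_markers, stride, 4)
            for k in range(4):
                buf |= codes[:, :, k] << (2 * k)
            fh.write(buf.tobytes())
    else:
        raise ValueError(f"unknown PLINK dialect {dialect!r}")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:3] != ["id", "sire", "dam"]:
        raise FormatError(f"{path}: expected columns id/sire/dam, got {list(df.columns)}")
    return Pedigree(df.itertuples(index=False, name=None))


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# QC, imputation, heterozygosity
# ---------------------------------------------------------------------------

def qc_filter(
    gd: GenotypeDataset,
    min_ind_call_rate: float = 0.95,
    min_snp_call_rate: float = 0.95,
    autosomes=None,
) -> GenotypeDataset:
    """Apply call-rate and autosome filters.

    Individuals are filtered first, then markers (call rates recomputed on
    the retained individuals); a call rate must strictly exceed its
    threshold to be kept.  ``autosomes``, if given, is the set of retained
    chromosome labels (string comparison).
    """
    for thr in (min_ind_call_rate, min_snp_call_rate):
        if not 0 <= thr <= 1:
            raise ValueError(f"call-rate threshold {thr} outside [0,1]")
    calls = gd.calls
    notes = list(gd.provenance)

    ind_rate = (calls != MISSING).mean(axis=1)
    keep_ind = ind_rate > min_ind_call_rate
    notes.append(
        f"qc_filter: removed {int((~keep_ind).sum())} of {gd.n_samples} individuals "
        f"(call rate <= {min_ind_call_rate})"
    )
    calls = calls[keep_ind]
    samples = [s for s, k in zip(gd.samples, keep_ind) if k]
    if not samples:
        raise ValueError("qc_filter removed every individual; review thresholds")

    keep_mk = np.ones(gd.n_markers, dtype=bool)
    if autosomes is not None:
        auto = {str(a) for a in autosomes}
        keep_mk &= np.array([str(c) in auto for c in gd.markers["chromosome"]])
        notes.append(f"qc_filter: removed {int((~keep_mk).sum())} non-autosomal markers")
    snp_rate = (calls != MISSING).mean(axis=0)
    low = snp_rate <= min_snp_call_rate
    notes.append(
        f"qc_filter: removed {int((low & keep_mk).sum())} markers "
        f"(call rate <= {min_snp_call_rate})"
    )
    keep_mk &= ~low
    if not keep_mk.any():
        raise ValueError("qc_filter removed every marker; review thresholds")
    markers = gd.markers.loc[keep_mk].reset_index(drop=True)
    return GenotypeDataset(samples, markers, calls[:, keep_mk], notes)


def impute_mode(gd: GenotypeDataset, seed=None) -> GenotypeDataset:
    """Replace each missing call by the marker's most frequent genotype.

    Ties break toward the lower dosage.  This is a deliberately simple
    stand-in for pedigree/haplotype imputation: post-QC missingness is
    below 5%, and the downstream scan only needs complete data.  The
    ``seed`` argument is accepted for interface stability; mode imputation
    is deterministic and does not use it.
    """
    if not gd.has_missing():
        return gd.copy()
    calls = gd.calls.copy()
    all_missing = []
    for j in range(gd.n_markers):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            all_missing.append(gd.markers["marker_id"][j])
            continue
        counts = np.bincount(obs, minlength=3)
        col[miss] = int(np.argmax(counts))  # argmax breaks ties toward lower dosage
    if all_missing:
        raise ValueError(f"markers with all calls missing: {all_missing}")
    notes = gd.provenance + ["impute_mode: mode imputation, ties toward lower dosage"]
    return GenotypeDataset(list(gd.samples), gd.markers.copy(), calls, notes)


def heterozygosity_percent(gd: GenotypeDataset) -> np.ndarray:
    """Per-sample heterozygosity: heterozygous SNPs x 100 / total SNPs."""
    if gd.has_missing():
        raise ValueError("missing calls present; run impute_mode first")
    return 100.0 * (gd.calls == 1).sum(axis=1) / gd.n_markers
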