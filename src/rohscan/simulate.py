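"""Synthetic sow datasets with the structure the ROH scan assumes.

The generator emulates a closed nucleus herd of Iberian-type sows: a small
founder pool, a few generations of matings with a tunable amount of
close-relative (full-sib) mating, gene dropping of founder haplotypes with
Poisson recombination, and repeated litter-size records simulated from
exactly the repeatability animal model the pipeline fits:

    y = parity effect + d * heterozygosity% + hys + u + p
        + sum(planted carrier effects) + e

Litter size is simulated on the continuous scale and by default rounded to
non-negative integers for output (Number Born Alive is Total Number Born
minus a Poisson-distributed loss, so NBA <= TNB holds by construction).

Planted unfavourable segments are realised through the founder haplotypes:
a chosen fraction of founder haplotypes share one identical allele pattern
across the planted interval, so that a predictable share of final-
generation sows is homozygous across it.  Carrier status is therefore a
property of the simulated genotypes themselves — Mendelian inheritance is
never violated — and the truth table records it per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeDataset,
    Pedigree,
    PhenotypeTable,
    heterozygosity_percent,
    write_plink,
)
from .mixed_model import VarianceComponents
from .relationships import a_matrix

__all__ = ["SimConfig", "SimOutput", "sim_pedigree", "sim_genotypes",
           "sim_phenotypes", "simulate", "fixture_bundle"]

#: Default variance components (squared piglets) typical of total number
#: born in a small closed sow line, paired with a heterozygosity slope of
#: 0.055 piglets per percent heterozygosity.
DEFAULT_VARCOMP = dict(sigma2_a=0.145, sigma2_p=0.366, sigma2_h=0.170, sigma2_e=2.901)


@dataclass
class SimConfig:
    n_founders: int = 24
    n_generations: int = 5
    offspring_per_generation: int = 132
    litter_size: int = 5
    mating_scheme: str = "partial_fullsib"  # random | circular | partial_fullsib
    inbreeding_intensity: float = 0.9  # probability that a mating is full-sib
    n_chromosomes: int = 18
    snps_per_chromosome: int = 120
    chromosome_length_bp: int = 130_000_000
    founder_maf_range: tuple = (0.15, 0.5)
    recomb_rate: float = 1.3  # expected crossovers per chromosome per meiosis
    varcomp_true: dict = field(default_factory=lambda: dict(DEFAULT_VARCOMP))
    het_slope_true: float = 0.055  # piglets per percent heterozygosity
    parity_effects: tuple = (6.0, 6.3, 6.4, 6.4, 6.2)
    n_hys: int = 100
    records_per_sow: int = 6
    nba_loss_mean: float = 0.27  # Poisson mean of TNB - NBA
    planted_effects: tuple = (
        ("5", 16_000_000, 38_000_000, -0.6),
        ("8", 37_000_000, 59_000_000, -0.9),
    )
    planted_carrier_freq: float = 0.3
    round_phenotypes: bool = True
    seed: int = 1

    def __post_init__(self):
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0 (0 = founders only)")
        for name in ("n_founders", "offspring_per_generation",
                     "litter_size", "n_chromosomes", "snps_per_chromosome",
                     "chromosome_length_bp", "n_hys", "records_per_sow"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_founders < 4:
            raise ValueError("need at least 4 founders (two of each sex)")
        if not 0 <= self.inbreeding_intensity <= 1:
            raise ValueError("inbreeding_intensity must lie in [0, 1]")
        if self.mating_scheme not in ("random", "circular", "partial_fullsib"):
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")
        if len(self.parity_effects) != 5:
            raise ValueError("parity_effects needs 5 values (classes 1..4 and 5+)")
        if any(v < 0 for v in self.varcomp_true.values()):
            raise ValueError("true variance components must be non-negative")
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for chrom, start, end, _eff in self.planted_effects:
            if str(chrom) not in chroms:
                raise ValueError(f"planted segment on unknown chromosome {chrom!r}")
            if not (1 <= start < end <= self.chromosome_length_bp):
                raise ValueError(
                    f"planted interval {start}-{end} outside chromosome of "
                    f"{self.chromosome_length_bp} bp"
                )


def adapt_planted_defaults(kwargs: dict) -> dict:
    """Drop default planted segments that fall outside an overridden genome.

    Only applies when ``planted_effects`` itself was not supplied: explicit
    planted intervals that do not fit remain a configuration error.
    """
    if "planted_effects" in kwargs:
        return kwargs
    n_chrom = kwargs.get("n_chromosomes", SimConfig.n_chromosomes)
    length = kwargs.get("chromosome_length_bp", SimConfig.chromosome_length_bp)
    chroms = {str(c + 1) for c in range(n_chrom)}
    default = SimConfig.__dataclass_fields__["planted_effects"].default
    kept = tuple(pe for pe in default
                 if str(pe[0]) in chroms and 1 <= pe[1] < pe[2] <= length)
    if len(kept) != len(default):
        kwargs = dict(kwargs, planted_effects=kept)
    return kwargs


@dataclass
class SimOutput:
    pedigree: Pedigree
    genotypes: GenotypeDataset  # phenotyped (= genotyped) sows only
    phenotypes: PhenotypeTable
    truth: dict  # latent values, see sim_phenotypes


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def sim_pedigree(cfg: SimConfig) -> Pedigree:
    """Founder population plus ``n_generations`` of litters.

    Sexes alternate within each sibship (and among founders).  Under
    ``partial_fullsib`` each mating is a brother-sister pair with
    probability ``inbreeding_intensity`` (when such a pair exists), which
    makes mean inbreeding of the last generation increase with the knob.
    The returned Pedigree carries ``sex`` ('F'/'M') and ``generation``
    dicts as attributes.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    triples, sex, generation = [], {}, {}
    founders = [f"F{k + 1:04d}" for k in range(cfg.n_founders)]
    for k, fid in enumerate(founders):
        triples.append((fid, None, None))
        sex[fid] = "F" if k % 2 == 0 else "M"
        generation[fid] = 0
    prev = [(fid, None) for fid in founders]  # (id, litter tag)

    for g in range(1, cfg.n_generations + 1):
        males = [i for i, _ in prev if sex[i] == "M"]
        females = [i for i, _ in prev if sex[i] == "F"]
        if not males or not females:
            raise ValueError(f"generation {g}: fewer than one parent of a sex available")
        litters = {}
        for i, tag in prev:
            if tag is not None:
                litters.setdefault(tag, []).append(i)
        sib_litters = [
            v for v in litters.values()
            if any(sex[i] == "M" for i in v) and any(sex[i] == "F" for i in v)
        ]
        n_matings = math.ceil(cfg.offspring_per_generation / cfg.litter_size)
        matings = []
        for k in range(n_matings):
            scheme = cfg.mating_scheme
            if scheme == "partial_fullsib" and sib_litters and \
                    rng.random() < cfg.inbreeding_intensity:
                lit = sib_litters[rng.integers(len(sib_litters))]
                sire = str(rng.choice([i for i in lit if sex[i] == "M"]))
                dam = str(rng.choice([i for i in lit if sex[i] == "F"]))
            elif scheme == "circular":
                sire = males[k % len(males)]
                dam = females[(k + 1) % len(females)]
            else:
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
            matings.append((sire, dam))
        new = []
        born = 0
        for lk, (sire, dam) in enumerate(matings):
            for j in range(cfg.litter_size):
                if born >= cfg.offspring_per_generation:
                    break
                iid = f"G{g}_{born + 1:04d}"
                triples.append((iid, sire, dam))
                # alternate within the sibship, offsetting by litter so odd
                # litter sizes do not skew the sex ratio
                sex[iid] = "F" if (j + lk) % 2 == 0 else "M"
                generation[iid] = g
                new.append((iid, (g, lk)))
                born += 1
        prev = new

    ped = Pedigree(triples)
    ped.sex = sex
    ped.generation = generation
    return ped


# ---------------------------------------------------------------------------
# Genotypes: gene dropping with planted shared haplotypes
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    m, L = cfg.snps_per_chromosome, cfg.chromosome_length_bp
    for c in range(1, cfg.n_chromosomes + 1):
        for j in range(m):
            pos = int(round((j + 1) * L / (m + 1)))
            rows.append((f"chr{c}_snp{j + 1:04d}", str(c), pos))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])


def planted_marker_index(markers: pd.DataFrame, chrom, start_bp, end_bp) -> np.ndarray:
    sel = (
        (markers["chromosome"].astype(str) == str(chrom))
        & (markers["position_bp"] >= start_bp)
        & (markers["position_bp"] <= end_bp)
    )
    idx = np.flatnonzero(sel.to_numpy())
    if idx.size == 0:
        raise ValueError(
            f"planted interval {chrom}:{start_bp}-{end_bp} spans no marker"
        )
    return idx


def _planted_hap_freq(target: float, mean_f: float) -> float:
    """Founder-haplotype frequency q with F*q + (1-F)*q^2 ~= target carriers."""
    a, b, c = (1 - mean_f), mean_f, -target
    q = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a) if a > 0 else target
    return min(max(q, 0.0), 1.0)


def sim_genotypes(ped: Pedigree, cfg: SimConfig, return_haplotypes: bool = False):
    """Gene-drop founder haplotypes through the pedigree.

    Founder alleles are drawn per locus at a minor-allele frequency from
    ``founder_maf_range``; each meiosis draws a Poisson number of crossovers
    per chromosome at uniform positions (no interference).  Planted
    intervals overwrite a calibrated fraction of *founder* haplotypes with
    one shared allele pattern, so downstream homozygosity (and hence
    carrier status) arises through ordinary inheritance.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    markers = _marker_map(cfg)
    m = len(markers)
    n = len(ped)
    for k, (i, s, d) in enumerate(ped.triples):
        for par in (ped.sire[k], ped.dam[k]):
            if par is not None and par >= k:
                raise ValueError(f"pedigree not sorted parents-first at ({i}, {s}, {d})")

    lo, hi = cfg.founder_maf_range
    maf = rng.uniform(lo, hi, size=m)
    founder_idx = [k for k in range(n) if ped.sire[k] is None and ped.dam[k] is None]
    H = np.zeros((n, 2, m), dtype=np.int8)
    for k in founder_idx:
        H[k] = (rng.random((2, m)) < maf).astype(np.int8)

    if cfg.planted_effects:
        F = np.diag(a_matrix(ped).values) - 1.0
        last_gen = [k for k in range(n) if k not in set(founder_idx)]
        mean_f = float(np.mean(F[last_gen])) if last_gen else 0.0
        q = _planted_hap_freq(cfg.planted_carrier_freq, mean_f)
        for chrom, start, end, _eff in cfg.planted_effects:
            idx = planted_marker_index(markers, chrom, start, end)
            pattern = (rng.random(idx.size) < 0.5).astype(np.int8)
            for k in founder_idx:
                for h in range(2):
                    if rng.random() < q:
                        H[k, h, idx] = pattern

    # chromosome blocks over the marker map
    chrom_labels = markers["chromosome"].to_numpy()
    pos = markers["position_bp"].to_numpy()
    blocks = []
    start = 0
    for j in range(1, m + 1):
        if j == m or chrom_labels[j] != chrom_labels[start]:
            blocks.append((start, j))
            start = j

    L = cfg.chromosome_length_bp
    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        if s is None and d is None:
            continue
        for h, par in enumerate((s, d)):
            gamete = np.empty(m, dtype=np.int8)
            for a, b in blocks:
                nx = rng.poisson(cfg.recomb_rate)
                startedh = int(rng.integers(2))
                if nx == 0:
                    choice = np.full(b - a, startedh)
                else:
                    xpos = np.sort(rng.uniform(0, L, size=nx))
                    seg = np.searchsorted(xpos, pos[a:b])
                    choice = (startedh + seg) % 2
                gamete[a:b] = H[par, choice, np.arange(a, b)]
            H[k, h] = gamete

    calls = (H[:, 0, :] + H[:, 1, :]).astype(np.int8)
    gd = GenotypeDataset(list(ped.ids), markers, calls, ["simulated by gene dropping"])
    return (gd, H) if return_haplotypes else gd


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def phenotyped_sows(ped: Pedigree) -> list:
    """Non-founder females: the sows that receive litter records."""
    founders = set(ped.founders())
    return [i for i in ped.ids if ped.sex[i] == "F" and i not in founders]


def sim_phenotypes(ped: Pedigree, gd: GenotypeDataset, cfg: SimConfig):
    """Simulate repeated litter records; returns (PhenotypeTable, truth).

    ``gd`` must hold genotypes for (at least) every phenotyped sow; the
    heterozygosity covariate is computed by the same operation the pipeline
    uses.  Truth holds breeding values, permanent and hys effects,
    residuals, the continuous-scale traits and per-segment carrier flags.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    vc = cfg.varcomp_true
    sows = phenotyped_sows(ped)
    missing = [s for s in sows if s not in gd.samples]
    if missing:
        raise ValueError(f"phenotyped sows lack genotypes: {missing[:5]}")

    # additive values down the pedigree with Mendelian sampling variance
    n = len(ped)
    F = np.diag(a_matrix(ped).values) - 1.0
    u = np.zeros(n)
    sa = math.sqrt(vc["sigma2_a"]) if vc["sigma2_a"] > 0 else 0.0
    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        if s is None and d is None:
            u[k] = rng.normal(0.0, sa)
        else:
            mean = 0.5 * ((u[s] if s is not None else 0.0) + (u[d] if d is not None else 0.0))
            if s is not None and d is not None:
                msv = 0.5 - 0.25 * (F[s] + F[d])
            else:
                known = s if s is not None else d
                msv = 0.75 - 0.25 * F[known]
            u[k] = mean + rng.normal(0.0, math.sqrt(msv) * sa)

    sow_pos = {s: gd.samples.index(s) for s in sows}
    sub = GenotypeDataset([s for s in sows], gd.markers,
                          gd.calls[[sow_pos[s] for s in sows]], [])
    het = dict(zip(sows, heterozygosity_percent(sub)))

    carrier = {}
    for chrom, start, end, eff in cfg.planted_effects:
        idx = planted_marker_index(gd.markers, chrom, start, end)
        hom = (sub.calls[:, idx] != 1).all(axis=1)
        carrier[(str(chrom), start, end)] = dict(zip(sows, hom.astype(int)))

    hys_eff = rng.normal(0.0, math.sqrt(vc["sigma2_h"]), size=cfg.n_hys)
    p_eff = {s: rng.normal(0.0, math.sqrt(vc["sigma2_p"])) for s in sows}

    rows, truth_rows = [], []
    for s in sows:
        for r in range(1, cfg.records_per_sow + 1):
            parity = min(r, 5)
            hys = int(rng.integers(cfg.n_hys))
            e = rng.normal(0.0, math.sqrt(vc["sigma2_e"]))
            yc = (
                cfg.parity_effects[parity - 1]
                + cfg.het_slope_true * het[s]
                + hys_eff[hys]
                + u[ped.index[s]]
                + p_eff[s]
                + e
            )
            for (key, eff) in zip(carrier, (pe[3] for pe in cfg.planted_effects)):
                yc += eff * carrier[key][s]
            dead = int(rng.poisson(cfg.nba_loss_mean))
            if cfg.round_phenotypes:
                tnb = max(int(round(yc)), 0)
                nba = max(tnb - dead, 0)
            else:
                tnb = yc
                nba = yc - dead
            rows.append((s, parity, f"hys{hys + 1:03d}", tnb, nba))
            truth_rows.append((s, parity, f"hys{hys + 1:03d}", u[ped.index[s]],
                               p_eff[s], hys_eff[hys], e, yc, yc - dead, het[s]))

    phen = PhenotypeTable(pd.DataFrame(rows, columns=PhenotypeTable.COLUMNS))
    truth_records = pd.DataFrame(
        truth_rows,
        columns=["sow", "parity", "hys", "u", "p", "hys_effect", "e",
                 "tnb_continuous", "nba_continuous", "het_percent"],
    )
    truth = {
        "records": truth_records,
        "u": dict(zip(ped.ids, u)),
        "p": p_eff,
        "hys_effects": hys_eff,
        "het_percent": het,
        "carriers": carrier,
        "varcomp_true": dict(vc),
        "het_slope_true": cfg.het_slope_true,
    }
    return phen, truth


def simulate(cfg: SimConfig) -> SimOutput:
    """Full synthetic study: pedigree, sow genotypes, records, truth."""
    ped = sim_pedigree(cfg)
    gd_all = sim_genotypes(ped, cfg)
    phen, truth = sim_phenotypes(ped, gd_all, cfg)
    sows = phenotyped_sows(ped)
    pos = [gd_all.samples.index(s) for s in sows]
    gd = GenotypeDataset(sows, gd_all.markers, gd_all.calls[pos],
                         ["simulated; phenotyped sows only"])
    return SimOutput(ped, gd, phen, truth)


def fixture_bundle(cfg: SimConfig, out_dir, binary: bool = False) -> dict:
    """Write a complete on-disk dataset; returns the file paths.

    Emits PLINK text (optionally also binary) genotypes for the phenotyped
    sows, a pedigree TSV, a phenotype TSV and a per-record truth TSV.  All
    files are deterministic functions of the config (seed included).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    out = simulate(cfg)
    prefix = os.path.join(out_dir, "genotypes")
    write_plink(out.genotypes, prefix, dialect="text")
    paths = {"ped": prefix + ".ped", "map": prefix + ".map"}
    if binary:
        write_plink(out.genotypes, prefix, dialect="binary")
        paths.update(bed=prefix + ".bed", bim=prefix + ".bim", fam=prefix + ".fam")
    pedigree_path = os.path.join(out_dir, "pedigree.tsv")
    out.pedigree.write_tsv(pedigree_path)
    phen_path = os.path.join(out_dir, "phenotypes.tsv")
    out.phenotypes.write_tsv(phen_path)
    truth_path = os.path.join(out_dir, "truth.tsv")
    tr = out.truth["records"].copy()
    for k, key in enumerate(out.truth["carriers"], 1):
        tr[f"carrier_{key[0]}_{key[1]}_{key[2]}"] = [
            out.truth["carriers"][key][s] for s in tr["sow"]
        ]
    tr.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
    paths.update(pedigree=pedigree_path, phenotypes=phen_path, truth=truth_path)
    return paths
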