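"""End-to-end orchestration: QC -> heterozygosity -> ROH catalog ->
relationships -> REML -> heterozygosity slope -> per-segment scan -> summaries.

Driven by a flat ``key: value`` config (or a :class:`PipelineConfig` built in
code).  Every output is a TSV or JSON file in the output directory, and a
manifest records every parameter actually used, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genotypes as gio
from .genotypes import GenotypeDataset, Pedigree, PhenotypeTable
from .mixed_model import ModelSpec, VarianceComponents, ai_reml, fit_het_covariate
from .relationships import h_inverse
from .roh import build_catalog, detect_runs, summarize_catalog
from .scan import merge_regions, scan, summarize_scan
from .simulate import SimConfig, fixture_bundle, simulate

log = logging.getLogger("rohscan")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    simulate: bool = False
    sim: SimConfig | None = None
    genotypes: str | None = None
    genotype_format: str = "text"
    pedigree: str | None = None
    phenotypes: str | None = None
    min_ind_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    autosomes: list | None = None
    min_snps: int = 16
    min_freq: float = 0.05
    max_freq: float = 0.95
    blend_alpha: float = 0.95
    scan_het_covariate: bool = False
    scan_hys: bool = True
    df: float | None = None
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    traits: tuple = ("tnb", "nba")
    out_dir: str = "rohscan_out"
    seed: int = 1

    def __post_init__(self):
        real = [self.genotypes, self.pedigree, self.phenotypes]
        if self.simulate and any(real):
            raise ValueError("config mixes fixture mode with real input paths")
        if not self.simulate and not all(real):
            raise ValueError("need genotypes, pedigree and phenotypes paths "
                             "(or simulate: true)")
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        problems = []
        for k in ("min_ind_call_rate", "min_snp_call_rate"):
            v = getattr(self, k)
            if not 0 <= v <= 1:
                problems.append(f"{k}={v} outside [0,1]")
        if self.min_freq > self.max_freq:
            problems.append(f"min_freq={self.min_freq} > max_freq={self.max_freq}")
        if not 0 <= self.blend_alpha <= 1:
            problems.append(f"blend_alpha={self.blend_alpha} outside [0,1]")
        if self.min_snps < 1:
            problems.append(f"min_snps={self.min_snps} must be >= 1")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


_BOOL = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}

_CONFIG_KEYS = {
    f.name for f in dataclasses.fields(PipelineConfig) if f.name != "sim"
}
_SIM_KEYS = {f"sim_{f.name}" for f in dataclasses.fields(SimConfig)}


def _parse_value(key, raw):
    raw = raw.strip()
    if key == "autosomes":
        if "-" in raw and "," not in raw:
            a, b = raw.split("-")
            return [str(c) for c in range(int(a), int(b) + 1)]
        return [tok.strip() for tok in raw.split(",") if tok.strip()]
    if key == "traits":
        return tuple(tok.strip().lower() for tok in raw.split(","))
    if raw.lower() in _BOOL:
        return _BOOL[raw.lower()]
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def validate_config(text: str) -> PipelineConfig:
    """Parse flat ``key: value`` config text; report all problems at once."""
    values, sim_values, errors = {}, {}, []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            errors.append(f"line {ln}: expected 'key: value', got {line!r}")
            continue
        key, raw = line.split(":", 1)
        key = key.strip()
        if key in _CONFIG_KEYS:
            values[key] = _parse_value(key, raw)
        elif key in _SIM_KEYS:
            sim_values[key[4:]] = _parse_value(key, raw)
        else:
            close = difflib.get_close_matches(key, _CONFIG_KEYS | _SIM_KEYS, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            errors.append(f"line {ln}: unknown key {key!r}{hint}")
    if errors:
        raise ValueError("configuration errors:\n  " + "\n  ".join(errors))
    if sim_values and not values.get("simulate"):
        values["simulate"] = True
    sim = None
    if values.get("simulate"):
        sim_values.setdefault("seed", values.get("seed", 1))
        try:
            from .simulate import adapt_planted_defaults
            sim = SimConfig(**adapt_planted_defaults(sim_values))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"configuration errors:\n  sim: {exc}") from exc
    try:
        return PipelineConfig(sim=sim, **values)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"configuration errors:\n  {exc}") from exc


def _manifest_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output paths and key results.

    Stage order and outputs: QC report, heterozygosity table, run/catalog
    TSVs with a descriptive summary, variance-component report, covariate
    estimate report, per-trait scan TSV (merged layout), significance
    summary and merged-region TSVs, and a manifest of every parameter used.
    On failure a FAILED marker naming the stage is left in the output
    directory and the exception propagates.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs = {}
    stage = "setup"
    t0 = time.time()
    try:
        # ------------------------------------------------ inputs
        stage = "inputs"
        if cfg.simulate:
            fixture_dir = os.path.join(cfg.out_dir, "fixture")
            fixture_bundle(cfg.sim, fixture_dir)
            out = simulate(cfg.sim)
            gd_raw, ped, phen = out.genotypes, out.pedigree, out.phenotypes
        else:
            gd_raw = gio.read_plink(cfg.genotypes, dialect=cfg.genotype_format)
            ped = gio.read_pedigree(cfg.pedigree)
            phen = gio.read_phenotypes(cfg.phenotypes)
        log.info("inputs: %d samples, %d markers, %d pedigree, %d records (%.1fs)",
                 gd_raw.n_samples, gd_raw.n_markers, len(ped), len(phen),
                 time.time() - t0)

        # ------------------------------------------------ QC + imputation
        stage = "qc"
        gd = gio.qc_filter(gd_raw, cfg.min_ind_call_rate, cfg.min_snp_call_rate,
                           autosomes=cfg.autosomes)
        gd = gio.impute_mode(gd)
        qc_path = os.path.join(cfg.out_dir, "qc_report.txt")
        with open(qc_path, "w") as fh:
            fh.write("\n".join(gd.provenance) + "\n")
            fh.write(f"retained: {gd.n_samples} individuals, {gd.n_markers} markers\n")
        outputs["qc_report"] = qc_path

        stage = "heterozygosity"
        het_values = gio.heterozygosity_percent(gd)
        het = dict(zip(gd.samples, het_values))
        het_path = os.path.join(cfg.out_dir, "heterozygosity.tsv")
        pd.DataFrame({"sample": gd.samples, "het_percent": het_values}).to_csv(
            het_path, sep="\t", index=False, float_format="%.6f")
        outputs["heterozygosity"] = het_path

        # ------------------------------------------------ ROH catalog
        stage = "roh"
        runs = detect_runs(gd, min_snps=cfg.min_snps)
        catalog = build_catalog(runs, gd, cfg.min_freq, cfg.max_freq, cfg.min_snps)
        runs_path = os.path.join(cfg.out_dir, "runs.tsv")
        pd.DataFrame(
            [
                {"sample": r.sample, "chromosome": r.chromosome,
                 "start_bp": r.start_bp, "end_bp": r.end_bp, "n_snps": r.n_snps,
                 "length_bp": r.length_bp}
                for s in gd.samples for r in runs[s]
            ]
        ).to_csv(runs_path, sep="\t", index=False)
        catalog_path = os.path.join(cfg.out_dir, "catalog.tsv")
        catalog.to_frame().to_csv(catalog_path, sep="\t", index=False,
                                  float_format="%.6f")
        summary = summarize_catalog(runs, gd)
        roh_summary_path = os.path.join(cfg.out_dir, "roh_summary.json")
        with open(roh_summary_path, "w") as fh:
            json.dump({k: v for k, v in summary.items() if k != "coverage_percent"},
                      fh, indent=1, default=str)
        outputs.update(runs=runs_path, catalog=catalog_path,
                       roh_summary=roh_summary_path)
        log.info("roh: %d runs, %d catalog segments, coverage %.1f%%",
                 summary["n_runs"], len(catalog), summary["coverage_mean"])

        # ------------------------------------------------ relationships
        stage = "relationships"
        hinv = h_inverse(ped, gd, gd.samples, blend_alpha=cfg.blend_alpha)

        # ------------------------------------------------ per-trait models
        results = {}
        vc_rows, cov_rows = [], []
        scan_frames, summaries, regions = {}, {}, {}
        for trait in cfg.traits:
            stage = f"reml[{trait}]"
            spec = ModelSpec(trait=trait, het_covariate=True, hys=True, df=cfg.df)
            vc = ai_reml(phen, spec, hinv, het=het, tol=cfg.reml_tol,
                         max_iter=cfg.reml_max_iter)
            for comp, val in vc.as_dict().items():
                vc_rows.append({"trait": trait, "component": comp, "estimate": val,
                                "sampling_variance": vc.sampling_variances[comp]})
            stage = f"covariate[{trait}]"
            cov = fit_het_covariate(phen, spec, hinv, vc, het)
            cov_rows.append({"trait": trait, "estimate": cov.estimate,
                             "se": cov.se, "p_one_sided": cov.p_one_sided})
            stage = f"scan[{trait}]"
            scan_spec = ModelSpec(trait=trait, het_covariate=cfg.scan_het_covariate,
                                  hys=cfg.scan_hys, df=cfg.df)
            sdf = scan(catalog, phen, scan_spec, hinv, vc,
                       het=het if cfg.scan_het_covariate else None)
            scan_frames[trait] = sdf
            summaries[trait] = summarize_scan(sdf)
            regions[trait] = merge_regions(sdf)
            results[trait] = {"vc": vc, "covariate": cov}
            log.info("%s: REML %d iters, d=%.4f (p=%.3g), %d segments scanned",
                     trait, vc.iterations, cov.estimate, cov.p_one_sided, len(sdf))

        stage = "reports"
        vc_path = os.path.join(cfg.out_dir, "variance_components.tsv")
        pd.DataFrame(vc_rows).to_csv(vc_path, sep="\t", index=False,
                                     float_format="%.6f")
        cov_path = os.path.join(cfg.out_dir, "het_covariate.tsv")
        pd.DataFrame(cov_rows).to_csv(cov_path, sep="\t", index=False,
                                      float_format="%.6g")
        outputs.update(variance_components=vc_path, het_covariate=cov_path)

        # merged two-trait scan table
        key_cols = ["chromosome", "start_bp", "end_bp", "start_idx", "end_idx",
                    "n_snps", "n_carriers"]
        merged = None
        for trait in cfg.traits:
            sub = scan_frames[trait].rename(
                columns={"effect": f"effect_{trait}", "se": f"se_{trait}",
                         "p": f"p_{trait}", "q": f"q_{trait}"}
            ).drop(columns=["trait"])
            merged = sub if merged is None else merged.merge(sub, on=key_cols,
                                                             how="outer")
        scan_path = os.path.join(cfg.out_dir, "scan.tsv")
        (merged if merged is not None else pd.DataFrame()).to_csv(
            scan_path, sep="\t", index=False, float_format="%.6g")
        outputs["scan"] = scan_path

        skip_path = os.path.join(cfg.out_dir, "scan_skipped.tsv")
        skip_rows = [
            {"trait": t, "chromosome": c, "start_bp": s, "end_bp": e, "reason": r}
            for t in cfg.traits
            for (c, s, e, r) in scan_frames[t].attrs.get("skipped", [])
        ]
        pd.DataFrame(skip_rows,
                     columns=["trait", "chromosome", "start_bp", "end_bp", "reason"]
                     ).to_csv(skip_path, sep="\t", index=False)
        outputs["scan_skipped"] = skip_path

        summary_path = os.path.join(cfg.out_dir, "scan_summary.json")
        with open(summary_path, "w") as fh:
            json.dump({t: _jsonable(summaries[t]) for t in cfg.traits}, fh, indent=1)
        outputs["scan_summary"] = summary_path
        for trait in cfg.traits:
            rp = os.path.join(cfg.out_dir, f"regions_{trait}.tsv")
            regions[trait].to_csv(rp, sep="\t", index=False, float_format="%.6g")
            outputs[f"regions_{trait}"] = rp

        stage = "manifest"
        manifest = {
            "config": _jsonable(_manifest_dict(cfg)),
            "n_samples": gd.n_samples,
            "n_markers": gd.n_markers,
            "n_pedigree": len(ped),
            "n_records": len(phen),
            "n_runs": summary["n_runs"],
            "n_catalog_segments": len(catalog),
            "scan_rows": {t: len(scan_frames[t]) for t in cfg.traits},
            "scan_skipped": {t: len(scan_frames[t].attrs.get("skipped", []))
                             for t in cfg.traits},
            "outputs": outputs,
        }
        manifest_path = os.path.join(cfg.out_dir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        outputs["manifest"] = manifest_path
    except Exception as exc:
        with open(os.path.join(cfg.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    outputs["results"] = results
    outputs["catalog_size"] = len(catalog)
    return outputs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
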