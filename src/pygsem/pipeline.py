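"""End-to-end study pipeline: simulate -> QC -> LDSC -> factor models -> latent GWAS -> MR.

Driven by a flat YAML config (see :func:`default_config` and the packaged
demo config). Every stage derives its own RNG seed from the single global
seed by stable hashing of the stage name, so a rerun with the same config
reproduces every numeric output bit-identically; the run report records
SHA-256 hashes of the tabular outputs to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factor_models as fm
from . import mr as mr_mod
from .latent_gwas import latent_gwas, qsnp_filter
from .ldsc import build_S_V, correlation_report
from .simulate import (InstrumentRegistry, LDStructure, TruthModel,
                       plant_instruments, simulate_sumstats,
                       simulate_true_effects, write_ld_blocks, write_ld_scores,
                       write_sumstats)
from .sumstats import SumstatsTable, qc_filter, harmonize_panels, read_sumstats, standardize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_config",
           "default_config", "load_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31 - 1)


def default_config() -> dict:
    """The demo configuration: 11 synthetic traits in three genetic clusters.

    Heritabilities follow the published ranges for these phenotype classes
    (0.04-0.41); the loneliness trait loads 0.66 on the neurodevelopmental/
    mood factor only; instruments are planted in both causal directions
    (0.5 forward, 0.34 reverse). QC, clumping and significance thresholds
    are the standard ones (INFO > 0.9, MAF > 0.01, 10,000 kb / r2 < 0.001,
    p < 5e-8 with a 5e-7 sensitivity pass).
    """
    names = ["adhd", "anx", "asd", "mdd", "ptsd",
             "alc", "can", "smk", "bip", "scz", "lone"]
    loadings = {
        "NMD": {"adhd": 0.60, "anx": 0.65, "asd": 0.50, "mdd": 0.75, "ptsd": 0.70,
                "lone": 0.66},
        "SUT": {"alc": 0.55, "can": 0.60, "smk": 0.65},
        "DPF": {"bip": 0.70, "scz": 0.75},
    }
    h2 = {"adhd": 0.236, "anx": 0.079, "asd": 0.118, "mdd": 0.089, "ptsd": 0.050,
          "alc": 0.050, "can": 0.070, "smk": 0.090, "bip": 0.170, "scz": 0.412,
          "lone": 0.042}
    return {
        "seed": 1,
        "outdir": "pipeline_out",
        "traits": names,
        "synthetic": {
            "std_loadings": loadings,
            "factor_corr": {"NMD,SUT": 0.45, "NMD,DPF": 0.35, "SUT,DPF": 0.30},
            "trait_h2": h2,
            "sample_sizes": {n: 50_000 for n in names},
            "overlap_frac": 0.0,
            "phenotypic_corr_overlap": 0.0,
            "polygenicity": 1.0,
            "snps_per_chr": 2273,
            "n_chrom": 22,
            "instruments": {
                "n_per_direction": 12,
                "effect_size": 0.05,
                "causal_forward": 0.5,
                "causal_reverse": 0.34,
                "pleiotropy_shift": 0.0,
            },
        },
        "qc": {"info_min": 0.9, "maf_min": 0.01},
        "ldsc": {"n_blocks": 200},
        "parity": {"efa": "odd_chr", "cfa": "even_chr"},
        "pattern": {"NMD": ["adhd", "anx", "asd", "mdd", "ptsd"],
                    "SUT": ["alc", "can", "smk"],
                    "DPF": ["bip", "scz"]},
        "loneliness": "lone",
        "target_factor": "NMD",
        "qsnp": {"threshold": 5e-8, "filter_on": "exposure_only"},
        "mr": {"p_threshold": 5e-8, "p_sensitivity": 5e-7,
               "clump_kb": 10_000, "clump_r2": 0.001, "steiger": True,
               "methods": ["ivw", "egger", "wmedian", "wmode", "raps"]},
    }


@dataclass
class PipelineConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise ValueError(f"cannot parse config file {path}: {err}") from err
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return PipelineConfig(raw)


def validate_config(config: PipelineConfig | dict) -> list[str]:
    """Return a list of violation messages (empty when the config is valid)."""
    raw = config.raw if isinstance(config, PipelineConfig) else config
    out: list[str] = []
    if "seed" not in raw or raw["seed"] is None:
        out.append("seed: mandatory, missing")
    qc = raw.get("qc", {})
    for key in ("info_min", "maf_min"):
        v = qc.get(key)
        if v is not None and not (0 < v < 1):
            out.append(f"qc.{key}: must be in (0, 1), got {v}")
    mr = raw.get("mr", {})
    r2 = mr.get("clump_r2")
    if r2 is not None and not (0 < r2 < 1):
        out.append(f"mr.clump_r2: must be in (0, 1), got {r2}")
    for key in ("p_threshold", "p_sensitivity", "clump_kb"):
        v = mr.get(key)
        if v is not None and v <= 0:
            out.append(f"mr.{key}: must be positive, got {v}")
    q = raw.get("qsnp", {}).get("threshold")
    if q is not None and not (0 < q < 1):
        out.append(f"qsnp.threshold: must be in (0, 1), got {q}")
    parity = raw.get("parity", {})
    if parity.get("efa") and parity.get("efa") == parity.get("cfa"):
        out.append("parity: EFA and CFA assigned the same chromosome subset; "
                   "exploration and confirmation should use disjoint halves "
                   "(warning)")
    return out


@dataclass
class RunReport:
    config_fingerprint: str
    stages: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_fingerprint": self.config_fingerprint,
                       "stages": self.stages,
                       "output_hashes": self.output_hashes},
                      fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_truth(cfg: dict, names: list[str]) -> TruthModel:
    syn = cfg["synthetic"]
    factors = list(syn["std_loadings"])
    lam = np.zeros((len(names), len(factors)))
    for f, col in enumerate(factors):
        for trait, val in syn["std_loadings"][col].items():
            lam[names.index(trait), f] = float(val)
    phi = np.eye(len(factors))
    for key, val in syn["factor_corr"].items():
        a, b = [factors.index(x) for x in key.split(",")]
        phi[a, b] = phi[b, a] = float(val)
    h2 = np.array([float(syn["trait_h2"][n]) for n in names])
    n = np.array([float(syn["sample_sizes"][n]) for n in names])
    k = len(names)
    ov = float(syn.get("overlap_frac", 0.0))
    pc = float(syn.get("phenotypic_corr_overlap", 0.0))
    overlap = np.full((k, k), ov)
    np.fill_diagonal(overlap, 1.0)
    pheno = np.full((k, k), pc)
    np.fill_diagonal(pheno, 1.0)
    return TruthModel.from_standardized(lam, phi, h2, n, trait_names=names,
                                        overlap_frac=overlap,
                                        phenotypic_corr_overlap=pheno)


def _simulate_stage(cfg: PipelineConfig, outdir: Path, report: RunReport
                    ) -> tuple[list[SumstatsTable], pd.DataFrame, pd.DataFrame,
                               TruthModel, dict]:
    syn = cfg["synthetic"]
    names = list(cfg["traits"])
    truth = _build_truth(cfg.raw, names)
    ld = LDStructure.regular(snps_per_chr=int(syn.get("snps_per_chr", 1000)),
                             n_chrom=int(syn.get("n_chrom", 22)))
    eff = simulate_true_effects(truth, ld, float(syn.get("polygenicity", 1.0)),
                                seed=derive_seed(cfg.seed, "true_effects"))
    registries: dict[str, InstrumentRegistry] = {}
    inst = syn.get("instruments")
    if inst:
        lone_idx = names.index(cfg["loneliness"])
        factors = list(syn["std_loadings"])
        f_idx = factors.index(cfg["target_factor"])
        eff, reg_f = plant_instruments(
            truth, ld, int(inst["n_per_direction"]), float(inst["effect_size"]),
            seed=derive_seed(cfg.seed, "instruments_forward"),
            exposure=("trait", lone_idx), outcome=("factor", f_idx),
            causal_effect=float(inst["causal_forward"]),
            pleiotropy_shift=float(inst.get("pleiotropy_shift", 0.0)),
            true_effects=eff)
        eff, reg_r = plant_instruments(
            truth, ld, int(inst["n_per_direction"]), float(inst["effect_size"]),
            seed=derive_seed(cfg.seed, "instruments_reverse"),
            exposure=("factor", f_idx), outcome=("trait", lone_idx),
            causal_effect=float(inst["causal_reverse"]),
            pleiotropy_shift=float(inst.get("pleiotropy_shift", 0.0)),
            true_effects=eff,
            exclude_blocks=reg_f.table["block"].to_numpy())
        registries = {"forward": reg_f, "reverse": reg_r}
        protect = np.concatenate([reg_f.snp_indices, reg_r.snp_indices])
    else:
        protect = None
    tabs = simulate_sumstats(eff, truth, ld, seed=derive_seed(cfg.seed, "sumstats"),
                             protect=protect)
    tables = [SumstatsTable(t, name=n) for t, n in zip(tabs, names)]

    ld_scores = pd.DataFrame({"SNP": ld.snp_ids, "CHR": ld.chromosome,
                              "L2": ld.ld_scores})
    ld_ref = pd.DataFrame({"SNP": ld.snp_ids, "CHR": ld.chromosome,
                           "BP": ld.position, "BLOCK": ld.block_index,
                           "R2": np.repeat(ld.within_block_r2, ld.block_sizes)})
    truth.to_yaml(outdir / "truth.yaml")
    write_ld_scores(ld, outdir / "ld_scores.tsv")
    write_ld_blocks(ld, outdir / "ld_blocks.tsv")
    for t in tables:
        write_sumstats(t.df, outdir / f"sumstats_{t.name}.tsv")
    for direction, reg in registries.items():
        reg.table.to_csv(outdir / f"instruments_{direction}.tsv", sep="\t",
                         index=False, float_format="%.10g")
    report.record("simulate", n_snps=ld.n_snps, n_traits=len(tables),
                  n_blocks=ld.n_blocks,
                  planted={d: len(r.table) for d, r in registries.items()})
    return tables, ld_scores, ld_ref, truth, registries


def _load_stage(cfg: PipelineConfig, report: RunReport):
    """File-backed traits: read, standardize; LD scores/reference from TSV."""
    entries = cfg["trait_files"]
    tables = []
    for name, spec in entries.items():
        t = read_sumstats(spec["path"], column_map=spec.get("column_map"), name=name)
        tables.append(standardize(t))
    ld_scores = pd.read_csv(cfg["ld_scores"], sep="\t")
    ld_ref = pd.read_csv(cfg["ld_reference"], sep="\t")
    report.record("load", n_traits=len(tables),
                  rows={t.name: len(t) for t in tables})
    return tables, ld_scores, ld_ref, None, {}


def run_pipeline(config: PipelineConfig | dict, outdir: str | Path | None = None
                 ) -> RunReport:
    """Execute the full study-shaped run; returns the consolidated report.

    Stage failures are recorded in the report and downstream dependent
    stages are skipped rather than raising, so a partial run remains
    auditable.
    """
    if isinstance(config, dict):
        config = PipelineConfig(config)
    violations = [v for v in validate_config(config) if "(warning)" not in v]
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir or config.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    fingerprint = hashlib.sha256(
        yaml.safe_dump(config.raw, sort_keys=True).encode()).hexdigest()
    report = RunReport(config_fingerprint=fingerprint)

    # --- data stage
    if "synthetic" in config.raw:
        tables, ld_scores, ld_ref, truth, registries = _simulate_stage(
            config, outdir, report)
    else:
        tables, ld_scores, ld_ref, truth, registries = _load_stage(config, report)

    # --- QC
    qc = config.get("qc", {})
    before = {t.name: len(t) for t in tables}
    tables = [qc_filter(t, info_min=float(qc.get("info_min", 0.9)),
                        maf_min=float(qc.get("maf_min", 0.01))) for t in tables]
    report.record("qc", rows_before=before, rows_after={t.name: len(t) for t in tables},
                  info_min=qc.get("info_min", 0.9), maf_min=qc.get("maf_min", 0.01))

    # --- harmonization
    tables = harmonize_panels(tables)
    report.record("harmonize", n_snps=len(tables[0]))

    n_blocks = int(config.get("ldsc", {}).get("n_blocks", 200))
    parity = config.get("parity", {"efa": "odd_chr", "cfa": "even_chr"})

    # --- LDSC S/V
    try:
        gc_all = build_S_V(tables, ld_scores, subset="all", n_blocks=n_blocks)
        gc_odd = build_S_V(tables, ld_scores, subset=parity.get("efa", "odd_chr"),
                           n_blocks=n_blocks)
        gc_even = build_S_V(tables, ld_scores, subset=parity.get("cfa", "even_chr"),
                            n_blocks=n_blocks)
    except ValueError as err:
        report.record("ldsc", status="failed", error=str(err))
        report.to_json(outdir / "run_report.json")
        raise
    corr = correlation_report(gc_all)
    corr.to_frame().to_csv(outdir / "genetic_correlations.tsv", sep="\t",
                           index=False, float_format="%.10g")
    pd.DataFrame(gc_all.S, index=gc_all.traits, columns=gc_all.traits).to_csv(
        outdir / "S_all.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(gc_all.intercepts, index=gc_all.traits, columns=gc_all.traits
                 ).to_csv(outdir / "intercepts_all.tsv", sep="\t", float_format="%.10g")
    _heatmap(corr, outdir / "genetic_correlations.png")
    report.record("ldsc", n_snps={"all": gc_all.n_snps, "odd": gc_odd.n_snps,
                                  "even": gc_even.n_snps},
                  h2={t: gc_all.S[i, i] for i, t in enumerate(gc_all.traits)},
                  n_blocks=n_blocks)

    # --- PCA / EFA on the exploration half
    psychopath = [t for t in tables if t.name != config["loneliness"]]
    gc_odd_psy = build_S_V(psychopath, ld_scores,
                           subset=parity.get("efa", "odd_chr"), n_blocks=n_blocks)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        scree = fm.pca_scree(gc_odd_psy)
        efa = fm.efa_fit(gc_odd_psy, max(scree.n_retained, 1))
    scree.to_frame().to_csv(outdir / "scree.tsv", sep="\t", index=False,
                            float_format="%.10g")
    efa.to_frame().to_csv(outdir / "efa_loadings.tsv", sep="\t",
                          float_format="%.10g")
    report.record("factor_enumeration", eigenvalues=scree.eigenvalues,
                  n_retained=scree.n_retained,
                  efa_variance_explained=efa.variance_explained,
                  proposed_pattern=efa.proposed_pattern())

    # --- CFA + three loneliness structural models on the confirmation half
    pattern = {f: list(ind) for f, ind in config["pattern"].items()}
    models = fm.loneliness_models(gc_even, pattern, config["loneliness"],
                                  target_factor=config["target_factor"],
                                  seed=derive_seed(config.seed, "cfa"))
    fit_rows = []
    for label, fits in [("unadjusted", models.unadjusted),
                        ("adjusted", [models.adjusted]),
                        ("constrained", [models.constrained])]:
        for f in fits:
            fi = fm.fit_indices(f)
            fit_rows.append({"model": label, **fi, "converged": f.converged})
    pd.DataFrame(fit_rows).to_csv(outdir / "structural_fit_indices.tsv", sep="\t",
                                  index=False, float_format="%.10g")
    std = models.constrained.standardized()
    std.to_csv(outdir / "constrained_model_parameters.tsv", sep="\t",
               float_format="%.10g")
    target_path = f"LONE~{config['target_factor']}"
    path_row = std.loc[target_path]
    report.record("structural_models",
                  constrained_beta=path_row["std_est"],
                  constrained_beta_se=path_row["std_se"],
                  adjusted_paths={p: models.adjusted.standardized().loc[p, "std_est"]
                                  for p in models.adjusted.param_names
                                  if p.startswith("LONE~")},
                  fits=fit_rows, converged=not models.any_nonconverged)

    # --- latent-factor GWAS + Q_SNP
    lgw = latent_gwas(tables, gc_even, models.constrained, config["target_factor"])
    qcfg = config.get("qsnp", {})
    lgw_filtered, excluded = qsnp_filter(lgw, float(qcfg.get("threshold", 5e-8)))
    lgw_filtered.df.to_csv(outdir / f"latent_gwas_{config['target_factor']}.tsv",
                           sep="\t", index=False, float_format="%.10g")
    n_sig = int((lgw.df["P"] < config.get("mr", {}).get("p_threshold", 5e-8)).sum())
    report.record("latent_gwas", n_snps=len(lgw.df), n_significant=n_sig,
                  n_qsnp_excluded=len(excluded))

    # --- bidirectional MR at the primary and sensitivity thresholds
    lone = next(t for t in tables if t.name == config["loneliness"])
    mrcfg = config.get("mr", {})
    filter_on = qcfg.get("filter_on", "exposure_only")
    mr_tables = []
    for tag, pthr in [("primary", float(mrcfg.get("p_threshold", 5e-8))),
                      ("sensitivity", float(mrcfg.get("p_sensitivity", 5e-7)))]:
        latent_for_exposure = lgw_filtered
        latent_for_outcome = lgw_filtered if filter_on == "both" else lgw
        import warnings as _w2
        with _w2.catch_warnings():
            _w2.simplefilter("ignore")
            fwd = mr_mod._one_direction(
                lone, latent_for_outcome, ld_ref, pthr,
                float(mrcfg.get("clump_kb", 10_000)),
                float(mrcfg.get("clump_r2", 0.001)),
                bool(mrcfg.get("steiger", True)),
                derive_seed(config.seed, f"mr_fwd_{tag}"),
                tuple(mrcfg.get("methods", list(mr_mod.MRModel.METHODS))))
            rev = mr_mod._one_direction(
                latent_for_exposure, lone, ld_ref, pthr,
                float(mrcfg.get("clump_kb", 10_000)),
                float(mrcfg.get("clump_r2", 0.001)),
                bool(mrcfg.get("steiger", True)),
                derive_seed(config.seed, f"mr_rev_{tag}"),
                tuple(mrcfg.get("methods", list(mr_mod.MRModel.METHODS))))
        bid = mr_mod.BidirectionalResult(forward=fwd, reverse=rev)
        frame = bid.to_frame()
        frame.insert(0, "threshold", tag)
        mr_tables.append(frame)
        for direction, rep in [("forward", fwd), ("reverse", rev)]:
            fd = rep.forest_data()
            if len(fd):
                fd.to_csv(outdir / f"forest_{tag}_{direction}.tsv", sep="\t",
                          index=False, float_format="%.10g")
        report.record(f"mr_{tag}",
                      forward_status=fwd.status, reverse_status=rev.status,
                      forward_n=len(fwd.instruments) if fwd.instruments is not None else 0,
                      reverse_n=len(rev.instruments) if rev.instruments is not None else 0)
    mr_all = pd.concat(mr_tables, ignore_index=True)
    mr_all.to_csv(outdir / "mr_results.tsv", sep="\t", index=False,
                  float_format="%.10g")
    _forest_plot(mr_all, outdir / "mr_forest.png")

    # --- output hashes for the determinism contract (tabular outputs only)
    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.yaml")):
        report.output_hashes[p.name] = _hash_file(p)
    report.to_json(outdir / "run_report.json")
    return report


def _heatmap(corr, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.rg, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.traits)), corr.traits, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.traits)), corr.traits, fontsize=7)
    k = len(corr.traits)
    for i in range(k):
        for j in range(k):
            if i != j and corr.p_fdr[i, j] < 0.05:
                ax.text(j, i, "*", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="genetic correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _forest_plot(mr_all: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = mr_all[mr_all["threshold"] == "primary"]
    if len(sub) == 0:
        return
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(sub) + 1.5))
    labels = [f"{r.exposure}->{r.outcome}: {r.method}" for r in sub.itertuples()]
    y = np.arange(len(sub))[::-1]
    ax.errorbar(sub["beta"], y,
                xerr=[sub["beta"] - sub["ci_low"], sub["ci_high"] - sub["beta"]],
                fmt="o", capsize=2)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(y, labels, fontsize=7)
    ax.set_xlabel("causal estimate (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
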