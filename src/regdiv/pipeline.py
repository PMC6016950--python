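"""End-to-end orchestration: simulate -> quantify -> cis/trans -> sharing.

The pipeline runs the whole analysis on a synthetic two-cross study and
writes per-stage TSV tables, a JSON summary (category counts, median percent
cis, allelic-bias p, sharing correlations) and a run log with package
versions, the seed and every resolved threshold, sufficient to reproduce any
table exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cistrans, expression, genesets, io
from ._rng import substream
from .simulate import SimulationParams, simulate_study

logger = logging.getLogger("regdiv")


@dataclass
class PipelineConfig:
    """Resolved thresholds and sizes for one pipeline run.

    Defaults are the analysis constants the method prescribes: a 20-read
    minimum of pooled allele-informative reads, a 32-fold allelic-ratio cap,
    a 0.1 FPKM expression floor, 1% FDR on the cis and trans tests, 10% FDR
    on differential expression, and 10,000 bootstrap replicates for gene-set
    calibration (100,000 for correlation exceedance).
    """

    out_dir: str = "regdiv_run"
    seed: int = 0
    min_reads: int = 20
    max_fold: float = 32.0
    fpkm_min: float = 0.1
    fdr_cis_trans: float = 0.01
    fdr_de: float = 0.10
    bootstrap_geneset: int = 10_000
    bootstrap_correlation: int = 100_000
    gtest_mode: str = cistrans.DEFAULT_GTEST_MODE
    shared_trans: bool = True
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self):
        for name in ("min_reads", "max_fold", "fpkm_min", "fdr_cis_trans", "fdr_de"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolved(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "simulation"}
        d["simulation"] = self.simulation.to_dict()
        return d


def config_from_mapping(values: dict, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a flat ``key = value`` mapping.

    Simulation keys (``n_genes`` etc.) are routed to
    :class:`~regdiv.simulate.SimulationParams`; everything else to the
    pipeline.  ``seed`` overrides any seed in the mapping.
    """
    sim_fields = {f.name: f.type for f in fields(SimulationParams)}
    pipe_fields = {f.name for f in fields(PipelineConfig)} - {"simulation"}
    sim_kwargs: dict = {}
    pipe_kwargs: dict = {}
    for key, raw in values.items():
        if key in sim_fields:
            sim_kwargs[key] = type(getattr(SimulationParams(), key))(raw)
        elif key in pipe_fields:
            current = getattr(PipelineConfig(), key)
            if isinstance(current, bool):
                pipe_kwargs[key] = str(raw).lower() in ("1", "true", "yes")
            else:
                pipe_kwargs[key] = type(current)(raw)
        else:
            raise KeyError(f"unknown configuration key {key!r}")
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
        pipe_kwargs["seed"] = int(seed)
    elif "seed" in sim_kwargs:
        pipe_kwargs["seed"] = sim_kwargs["seed"]
    return PipelineConfig(simulation=SimulationParams(**sim_kwargs), **pipe_kwargs)


@dataclass
class CrossResult:
    regulatory: cistrans.RegulatoryResult
    de_flags: pd.DataFrame
    contingency: cistrans.ContingencyResult


@dataclass
class PipelineResult:
    config: PipelineConfig
    crosses: dict[str, CrossResult]
    summary: dict
    out_dir: Path


def _analyze_cross(
    cross: str,
    derived_pop: str,
    study,
    fpkm: pd.DataFrame,
    populations: pd.Series,
    factors: pd.Series,
    config: PipelineConfig,
) -> CrossResult:
    parental_log2 = expression.parental_log_ratio(fpkm, populations, derived_pop, "ancestral")
    pooled_parental = expression.pooled_normalized_counts(
        study.parental_counts.loc[fpkm.index],
        populations,
        (derived_pop, "ancestral"),
        factors=factors,
    )
    regulatory = cistrans.estimate_regulation(
        study.hybrid_allele_counts[cross],
        parental_log2,
        pooled_parental,
        fdr=config.fdr_cis_trans,
        min_reads=config.min_reads,
        max_fold=config.max_fold,
        gtest_mode=config.gtest_mode,
    )
    de = expression.call_differential_expression(
        study.parental_counts.loc[fpkm.index],
        populations,
        derived_pop,
        "ancestral",
        fdr=config.fdr_de,
        factors=factors,
    )
    contingency = cistrans.contingency_analysis(
        regulatory.table, de_mask=de["status"] != "ns"
    )
    return CrossResult(regulatory=regulatory, de_flags=de, contingency=contingency)


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full synthetic-to-report analysis.

    Stages: simulate the two-cross study, normalize and filter parental
    expression, decompose each cross's expression changes into cis and trans,
    classify genes, run the contingency and allelic-bias analyses, test a
    truth-derived gene set for convergent shift, and correlate the two
    crosses' expression/cis/trans changes.  Any stage failure aborts with the
    stage name.  Rerunning with the same config and seed reproduces every
    table byte for byte.
    """
    out_dir = io.ensure_dir(config.out_dir)
    stage = "simulate"
    try:
        study = simulate_study(config.simulation, shared_trans=config.shared_trans)

        stage = "quantify"
        populations = study.sample_info["population"]
        factors = expression.size_factors(study.parental_counts)
        fpkm_all = expression.compute_fpkm(
            study.parental_counts, study.transcript_lengths, factors
        )
        fpkm = expression.filter_low_expression(fpkm_all, config.fpkm_min)

        stage = "cistrans"
        crosses = {
            "cross1": _analyze_cross("cross1", "derived1", study, fpkm, populations, factors, config),
            "cross2": _analyze_cross("cross2", "derived2", study, fpkm, populations, factors, config),
        }

        stage = "genesets"
        log_fpkm = np.log2(fpkm + 1.0)
        rng = substream(config.seed, "geneset_bootstrap")
        # candidate set: genes with the largest true convergent upward (trans) shifts
        shared_t = study.truth["cross1"]["trans_log2"].reindex(fpkm.index).dropna()
        set_size = min(50, max(2, len(shared_t) // 20))
        members = shared_t.nlargest(set_size).index.tolist()
        candidate = genesets.GeneSet("true_shifted", tuple(members), "largest true trans upshifts")
        groups = populations.map(
            lambda p: "derived" if p.startswith("derived") else "ancestral"
        )
        shift = genesets.geneset_shift_test(log_fpkm, groups, candidate, "derived", "ancestral")
        boot = genesets.bootstrap_null(
            log_fpkm,
            set_size=len(candidate.present_in(log_fpkm.index)),
            B=config.bootstrap_geneset,
            statistic_fn=lambda m: abs(
                genesets.geneset_shift_test(log_fpkm, groups, m, "derived", "ancestral").statistic
            ),
            rng=rng,
            observed=abs(shift.statistic),
        )

        stage = "sharing"
        t1 = crosses["cross1"].regulatory.table
        t2 = crosses["cross2"].regulatory.table
        sharing = {}
        for label, col in (("expression", "log2_parental"), ("cis", "log2_cis"), ("trans", "log2_trans")):
            try:
                r, p = genesets.change_correlation(t1[col], t2[col])
            except ValueError:
                r, p = float("nan"), float("nan")
            sharing[label] = {"spearman_r": r, "p": p}
        shared_dir = genesets.direction_sharing(
            t1["log2_trans"],
            t2["log2_trans"],
            significant_a=crosses["cross1"].de_flags["status"] != "ns",
            significant_b=crosses["cross2"].de_flags["status"] != "ns",
        )

        stage = "report"
        summary = {
            "seed": config.seed,
            "n_genes": config.simulation.n_genes,
            "n_expressed": int(len(fpkm)),
            "crosses": {},
            "geneset_shift": {
                "statistic": shift.statistic,
                "p": shift.pvalue,
                "direction": shift.direction,
                "bootstrap_exceedance_p": boot.pvalue,
                "bootstrap_B": boot.B,
            },
            "sharing": sharing,
            "trans_direction_sharing": {
                "shared_up": shared_dir.shared_up,
                "shared_down": shared_dir.shared_down,
                "opposed": shared_dir.opposed,
                "shared_fraction": shared_dir.shared_fraction,
            },
        }
        for cross, res in crosses.items():
            table = res.regulatory.table
            summary["crosses"][cross] = {
                "n_quantifiable": res.regulatory.n_tested,
                "category_counts": {
                    k: int(v) for k, v in res.regulatory.category_counts().items()
                },
                "median_percent_cis": float(np.nanmedian(table["percent_cis"]) * 100.0),
                "allelic_bias_p": res.regulatory.bias_p,
                "contingency": res.contingency.table.to_dict(),
                "contingency_binomial_p": {
                    k: (None if np.isnan(v) else float(v))
                    for k, v in res.contingency.binomial_p.items()
                },
                "contingency_rows_p": res.contingency.rows_comparison_p,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(config=config, crosses=crosses, summary=summary, out_dir=out_dir)
    if write:
        _write_outputs(result, study, fpkm, factors)
    return result


def _write_outputs(result: PipelineResult, study, fpkm: pd.DataFrame, factors: pd.Series) -> None:
    out = result.out_dir
    io.write_table(study.parental_counts, out / "parental_counts.tsv")
    io.write_table(study.sample_info, out / "samples.tsv")
    io.write_table(study.transcript_lengths.to_frame(), out / "transcript_lengths.tsv")
    io.write_table(fpkm, out / "fpkm.tsv")
    io.write_table(factors.to_frame(), out / "size_factors.tsv")
    for cross, res in result.crosses.items():
        io.write_allele_counts(
            study.hybrid_allele_counts[cross], out / f"allele_counts_{cross}.tsv"
        )
        io.write_table(res.regulatory.table, out / f"regulatory_{cross}.tsv")
        io.write_table(res.de_flags, out / f"de_flags_{cross}.tsv")
        io.write_table(study.truth[cross], out / f"truth_{cross}.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    io.write_config(_flatten(result.config.resolved()), out / "resolved_config.txt")
    _write_log(out / "run.log", result.config)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{prefix}{k}."))
        else:
            out[f"{prefix}{k}"] = v
    return out


def _write_log(path: Path, config: PipelineConfig) -> None:
    import scipy
    import statsmodels

    lines = [
        f"regdiv {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}, "
        f"statsmodels {statsmodels.version.version if hasattr(statsmodels, 'version') else statsmodels.__version__}",
        f"seed {config.seed}",
        "resolved config:",
    ]
    lines += [f"  {k} = {v}" for k, v in _flatten(config.resolved()).items()]
    Path(path).write_text("\n".join(lines) + "\n")
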