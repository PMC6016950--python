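"""Synthetic data with known cis and trans regulatory effects.

The generator reproduces the statistical structure the downstream analysis
assumes, for a study contrasting an ancestral population with one or two
independently derived populations:

* Per gene, a log2 *cis* effect ``c`` and a log2 *trans* effect ``t``.  The
  true parental log2 expression ratio (derived over ancestral) is exactly
  ``c + t``.
* Parental RNA-seq counts are negative-binomial around a per-gene baseline
  depth, with per-sample library size factors.
* F1-hybrid allele-specific counts: both alleles share one trans environment,
  so the derived-allele read fraction depends on ``c`` alone,
  ``f(c) = 2^c / (1 + 2^c)``; per replicate the total is negative-binomial
  and the derived-allele count binomial.
* Trio variant tables (two parents + F1) with informative records on
  informative genes plus labeled decoy records that must be filtered out.
* Optionally, sequence-level reads drawn from the two allele sequences, each
  carrying its true allele of origin for assignment-accuracy tests.

Defaults emulate the study design the analysis targets: three parental
replicates per population, five hybrid replicates per cross, ~10^4 genes of
which ~60% carry an informative variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from .errors import ConfigurationError
from .phasing import PseudoTranscriptome, VariantTrioCall, build_pseudotranscriptome

_LN2 = math.log(2.0)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model.

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    n_parental_reps, n_hybrid_reps
        Replicates per parental population and per F1 cross.
    mean_depth
        Expected reads per gene per replicate (the per-gene baseline is
        log-normal around this mean with log-sd ``depth_spread``).
    nb_dispersion
        Negative-binomial dispersion; variance = mu + dispersion * mu**2.
        Zero recovers Poisson counts.
    cis_sd, trans_sd
        Standard deviations of the centered normal log2 effect distributions.
    frac_null
        Fraction of genes with exactly zero cis and trans effect.
    frac_uninformative
        Fraction of genes carrying no informative variant (no allele-specific
        signal recoverable).
    variant_density
        Informative variants per kilobase of collapsed transcript.
    read_length, error_rate
        Sequence-level read simulation only: read length in bases and
        per-base substitution probability.
    depth_spread
        SD of the natural log of the per-gene baseline depth.
    seed
        Root seed; fully determines every output.
    """

    n_genes: int = 10_000
    n_parental_reps: int = 3
    n_hybrid_reps: int = 5
    mean_depth: float = 200.0
    nb_dispersion: float = 0.01
    cis_sd: float = 0.5
    trans_sd: float = 0.5
    frac_null: float = 0.5
    frac_uninformative: float = 0.4
    variant_density: float = 2.0
    read_length: int = 100
    error_rate: float = 0.001
    depth_spread: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_null", "frac_uninformative", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_parental_reps", "n_hybrid_reps", "mean_depth", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("nb_dispersion", "cis_sd", "trans_sd", "variant_density", "depth_spread"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    gene_id: str
    sequence: str
    true_allele: str  # 'derived' or 'ancestral'


@dataclass
class SyntheticDataset:
    """One cross (derived x ancestral) worth of synthetic data."""

    params: SimulationParams
    truth: pd.DataFrame  # index gene_id; cis_log2, trans_log2, informative
    parental_counts: pd.DataFrame  # genes x samples
    sample_info: pd.DataFrame  # sample -> population, replicate
    hybrid_allele_counts: pd.DataFrame  # long: gene_id, replicate, derived_count, ancestral_count
    transcript_lengths: pd.Series
    trio_variants: list[VariantTrioCall] = field(default_factory=list)
    transcripts: dict[str, str] = field(default_factory=dict)
    reads: dict[str, list[SimulatedRead]] = field(default_factory=dict)


@dataclass
class StudyDataset:
    """Two derived populations against a shared ancestral population."""

    params: SimulationParams
    truth: dict[str, pd.DataFrame]  # cross name -> truth table
    parental_counts: pd.DataFrame  # genes x samples, 3 populations
    sample_info: pd.DataFrame
    hybrid_allele_counts: dict[str, pd.DataFrame]  # cross name -> long table
    transcript_lengths: pd.Series


def gene_ids(n_genes: int) -> pd.Index:
    width = max(4, len(str(n_genes)))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene_id")


def allele_fraction(c):
    """Expected derived-allele read fraction for log2 cis effect ``c``.

    ``2^c / (1 + 2^c)``, evaluated as a logistic for numerical stability.
    Strictly increasing, maps the real line onto (0, 1), and satisfies
    ``allele_fraction(-c) == 1 - allele_fraction(c)``.
    """
    return expit(np.asarray(c, dtype=float) * _LN2)


def generate_effects(params: SimulationParams, stream: str = "effects") -> pd.DataFrame:
    """Draw true per-gene regulatory effects.

    A fraction ``frac_null`` of genes gets ``c = t = 0`` exactly; the rest
    draw independently from N(0, cis_sd^2) and N(0, trans_sd^2).  A fraction
    ``frac_uninformative`` (independent of the null status) is flagged as
    carrying no informative variant.

    Returns a table indexed by gene_id with columns ``cis_log2``,
    ``trans_log2`` and boolean ``informative``.
    """
    rng = substream(params.seed, stream)
    n = params.n_genes
    c = rng.normal(0.0, params.cis_sd, size=n) if params.cis_sd > 0 else np.zeros(n)
    t = rng.normal(0.0, params.trans_sd, size=n) if params.trans_sd > 0 else np.zeros(n)
    n_null = int(round(params.frac_null * n))
    null_idx = rng.choice(n, size=n_null, replace=False)
    c[null_idx] = 0.0
    t[null_idx] = 0.0
    n_uninf = int(round(params.frac_uninformative * n))
    informative = np.ones(n, dtype=bool)
    informative[rng.choice(n, size=n_uninf, replace=False)] = False
    return pd.DataFrame(
        {"cis_log2": c, "trans_log2": t, "informative": informative},
        index=gene_ids(n),
    )


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + dispersion * mu**2."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p)


def _baseline_depth(rng: np.random.Generator, params: SimulationParams, n: int) -> np.ndarray:
    """Per-gene baseline depth, log-normal with mean ``mean_depth``."""
    s = params.depth_spread
    return rng.lognormal(mean=math.log(params.mean_depth) - 0.5 * s * s, sigma=s, size=n)


def simulate_parental_counts(
    truth: pd.DataFrame,
    params: SimulationParams,
    derived_pops: tuple[str, ...] = ("derived",),
    ancestral_pop: str = "ancestral",
    effect_columns: Mapping[str, tuple[str, str]] | None = None,
    stream: str = "parental",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate parental count matrices for one ancestral and >=1 derived pops.

    The ancestral per-gene mean is the shared log-normal baseline; each
    derived population's mean is that baseline times ``2**(c + t)`` for its
    own effects.  Per-sample library size factors are log-normal (sigma=0.2)
    so normalization genuinely matters downstream.

    Parameters
    ----------
    effect_columns
        Maps a derived population name to the ``(cis, trans)`` column pair of
        ``truth`` holding its effects; defaults to ``(cis_log2, trans_log2)``
        for every derived population.

    Returns
    -------
    (counts, sample_info): genes x samples integer counts, and per-sample
    metadata with columns ``population`` and ``replicate``.
    """
    rng = substream(params.seed, stream)
    n = len(truth)
    base_mu = _baseline_depth(rng, params, n)
    if effect_columns is None:
        effect_columns = {pop: ("cis_log2", "trans_log2") for pop in derived_pops}

    columns: dict[str, np.ndarray] = {}
    info_rows = []
    for pop in (ancestral_pop, *derived_pops):
        if pop == ancestral_pop:
            mu_pop = base_mu
        else:
            c_col, t_col = effect_columns[pop]
            mu_pop = base_mu * np.exp2(truth[c_col].to_numpy() + truth[t_col].to_numpy())
        for rep in range(1, params.n_parental_reps + 1):
            sf = rng.lognormal(mean=0.0, sigma=0.2)
            name = f"{pop}_{rep}"
            columns[name] = _nb_counts(rng, mu_pop * sf, params.nb_dispersion)
            info_rows.append((name, pop, rep))
    counts = pd.DataFrame(columns, index=truth.index)
    sample_info = pd.DataFrame(
        info_rows, columns=["sample", "population", "replicate"]
    ).set_index("sample")
    return counts, sample_info


def simulate_hybrid_allele_counts(
    truth: pd.DataFrame,
    params: SimulationParams,
    cis_column: str = "cis_log2",
    stream: str = "hybrid",
) -> pd.DataFrame:
    """Simulate per-replicate allele-specific counts in F1 hybrids.

    Per gene and replicate the total informative read count is
    negative-binomial around a log-normal baseline times a per-replicate size
    factor; the derived-allele count is binomial with success probability
    ``allele_fraction(c)``.  The trans effect moves both alleles equally and
    therefore never enters the allele fraction — the identifying assumption
    of the F1 design.  Genes without an informative variant are emitted with
    missing allele counts.

    Returns a long table: ``gene_id, replicate, derived_count,
    ancestral_count`` (nullable integers).
    """
    rng = substream(params.seed, stream)
    n = len(truth)
    base_mu = _baseline_depth(rng, params, n)
    frac = allele_fraction(truth[cis_column].to_numpy())
    informative = truth["informative"].to_numpy()

    frames = []
    for rep in range(1, params.n_hybrid_reps + 1):
        sf = rng.lognormal(mean=0.0, sigma=0.2)
        total = _nb_counts(rng, base_mu * sf, params.nb_dispersion)
        derived = rng.binomial(total, frac)
        frame = pd.DataFrame(
            {
                "gene_id": truth.index,
                "replicate": f"hyb_{rep}",
                "derived_count": pd.array(derived, dtype="Int64"),
                "ancestral_count": pd.array(total - derived, dtype="Int64"),
            }
        )
        frame.loc[~informative, ["derived_count", "ancestral_count"]] = pd.NA
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_transcript_lengths(
    params: SimulationParams, stream: str = "lengths"
) -> pd.Series:
    """Log-normal transcript lengths (median ~1.5 kb), floored at 3 read lengths."""
    rng = substream(params.seed, stream)
    lengths = rng.lognormal(mean=math.log(1500.0), sigma=0.4, size=params.n_genes)
    floor = 3 * params.read_length
    return pd.Series(
        np.maximum(lengths.astype(int), floor), index=gene_ids(params.n_genes), name="length"
    )


def simulate_transcripts(
    transcript_lengths: pd.Series, params: SimulationParams, stream: str = "transcripts"
) -> dict[str, str]:
    """Uniform-random reference transcript sequences."""
    rng = substream(params.seed, stream)
    out = {}
    for gene, length in transcript_lengths.items():
        out[gene] = rng.choice(_BASES, size=int(length)).tobytes().decode("ascii")
    return out


_DECOY_KINDS = ("parent_het", "f1_hom", "multiallelic", "missing")


def _random_substitution(rng: np.random.Generator, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[rng.integers(len(others))]


def simulate_trio_variants(
    truth: pd.DataFrame,
    transcript_lengths: pd.Series,
    params: SimulationParams,
    transcripts: Mapping[str, str] | None = None,
    stream: str = "variants",
) -> list[VariantTrioCall]:
    """Emit trio genotype calls: informative records plus labeled decoys.

    Informative genes receive a Poisson(variant_density * length / 1000)
    number of informative records (floored at one so the gene is genuinely
    informative); every gene additionally receives ~Poisson(1) decoy records
    — a heterozygous parent, a homozygous F1, a multiallelic site or a
    missing genotype — which the informativeness filter must remove.
    Uninformative genes receive decoys only.
    """
    rng = substream(params.seed, stream)
    calls: list[VariantTrioCall] = []
    for gene in truth.index:
        length = int(transcript_lengths.loc[gene])
        seq = transcripts.get(gene) if transcripts is not None else None
        informative = bool(truth.loc[gene, "informative"])
        n_inf = 0
        if informative:
            lam = params.variant_density * length / 1000.0
            n_inf = max(1, int(rng.poisson(lam)))
        n_decoy = int(rng.poisson(1.0))
        n_total = n_inf + n_decoy
        if n_total == 0:
            continue
        positions = rng.choice(length, size=min(n_total, length), replace=False)
        kinds = ["informative"] * n_inf + [
            _DECOY_KINDS[rng.integers(len(_DECOY_KINDS))] for _ in range(n_decoy)
        ]
        for pos, kind in zip(positions, kinds):
            pos = int(pos)
            ref = seq[pos] if seq is not None else "ACGT"[rng.integers(4)]
            alt = _random_substitution(rng, ref)
            derived_is_alt = bool(rng.integers(2))
            hom_alt, hom_ref = (1, 1), (0, 0)
            gt1, gt2 = (hom_alt, hom_ref) if derived_is_alt else (hom_ref, hom_alt)
            gt_hyb: tuple[int, int] | None = (0, 1)
            alt_field = alt
            if kind == "parent_het":
                gt1 = (0, 1)
            elif kind == "f1_hom":
                gt_hyb = (1, 1)
            elif kind == "multiallelic":
                # second ALT distinct from both ref and the first alt
                third = [b for b in "ACGT" if b not in (ref, alt)]
                alt_field = alt + "," + third[int(rng.integers(len(third)))]
            elif kind == "missing":
                gt_hyb = None
            calls.append(
                VariantTrioCall(
                    gene_id=gene,
                    pos=pos,
                    ref=ref,
                    alt=alt_field,
                    gt_parent1=gt1,
                    gt_parent2=gt2,
                    gt_hybrid=gt_hyb,
                    kind=kind,
                )
            )
    return calls


def true_pseudotranscriptomes(dataset: "SyntheticDataset") -> dict[str, PseudoTranscriptome]:
    """Build the ground-truth allele sequence pairs from the simulated trios."""
    pseudos = {}
    for gene, seq in dataset.transcripts.items():
        variants = [v for v in dataset.trio_variants if v.gene_id == gene]
        pseudos[gene] = build_pseudotranscriptome(gene, seq, variants)
    return pseudos


def simulate_reads(
    dataset: "SyntheticDataset",
    params: SimulationParams | None = None,
    stream: str = "reads",
) -> dict[str, list[SimulatedRead]]:
    """Draw labeled reads for each hybrid replicate from the allele sequences.

    Reads start uniformly along the allele transcript, in numbers given by
    the gene's simulated allele counts, with independent per-base
    substitution errors.  Each read records its true allele of origin so
    assignment accuracy can be scored exactly.  Genes shorter than the read
    length are skipped with a warning.
    """
    import warnings

    params = params or dataset.params
    if not dataset.transcripts:
        raise ConfigurationError("dataset has no transcript sequences; simulate with sequences")
    rng = substream(params.seed, stream)
    pseudos = true_pseudotranscriptomes(dataset)
    rl = params.read_length
    out: dict[str, list[SimulatedRead]] = {}
    for replicate, group in dataset.hybrid_allele_counts.groupby("replicate", sort=True):
        reads: list[SimulatedRead] = []
        for row in group.itertuples(index=False):
            if pd.isna(row.derived_count):
                continue
            pseudo = pseudos[row.gene_id]
            if len(pseudo.derived_seq) < rl:
                warnings.warn(f"{row.gene_id}: transcript shorter than read length; skipped")
                continue
            for allele, n_reads, seq in (
                ("derived", int(row.derived_count), pseudo.derived_seq),
                ("ancestral", int(row.ancestral_count), pseudo.ancestral_seq),
            ):
                if n_reads == 0:
                    continue
                starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
                for j, start in enumerate(starts):
                    bases = list(seq[start : start + rl])
                    if params.error_rate > 0:
                        errs = np.nonzero(rng.random(rl) < params.error_rate)[0]
                        for e in errs:
                            bases[e] = _random_substitution(rng, bases[e])
                    reads.append(
                        SimulatedRead(
                            read_id=f"{row.gene_id}|{replicate}|{allele}|{j}",
                            gene_id=row.gene_id,
                            sequence="".join(bases),
                            true_allele=allele,
                        )
                    )
        out[str(replicate)] = reads
    return out


def simulate_dataset(
    params: SimulationParams,
    with_sequences: bool = False,
    with_reads: bool = False,
) -> SyntheticDataset:
    """Generate a complete single-cross dataset under ``params.seed``."""
    truth = generate_effects(params)
    counts, sample_info = simulate_parental_counts(truth, params)
    hybrid = simulate_hybrid_allele_counts(truth, params)
    lengths = simulate_transcript_lengths(params)
    transcripts = simulate_transcripts(lengths, params) if (with_sequences or with_reads) else {}
    variants = simulate_trio_variants(
        truth, lengths, params, transcripts=transcripts or None
    )
    dataset = SyntheticDataset(
        params=params,
        truth=truth,
        parental_counts=counts,
        sample_info=sample_info,
        hybrid_allele_counts=hybrid,
        transcript_lengths=lengths,
        trio_variants=variants,
        transcripts=transcripts,
    )
    if with_reads:
        dataset.reads = simulate_reads(dataset, params)
    return dataset


def simulate_study(
    params: SimulationParams,
    shared_trans: bool = True,
) -> StudyDataset:
    """Two derived populations against one shared ancestral population.

    Emulates convergent evolution at the trans level: with
    ``shared_trans=True`` (default) the two derived populations share the
    same per-gene trans effect while drawing independent cis effects — the
    generative picture in which a common regulatory environment has evolved
    twice while the linked cis changes are population-specific.  With
    ``shared_trans=False`` both effect sets are independent.
    """
    truth1 = generate_effects(params, stream="effects")
    truth2 = generate_effects(params, stream="effects2")
    if shared_trans:
        truth2 = truth2.assign(trans_log2=truth1["trans_log2"].to_numpy())
    combined = pd.DataFrame(
        {
            "cis1": truth1["cis_log2"],
            "trans1": truth1["trans_log2"],
            "cis2": truth2["cis_log2"],
            "trans2": truth2["trans_log2"],
        },
        index=truth1.index,
    )
    counts, sample_info = simulate_parental_counts(
        combined.assign(informative=True),
        params,
        derived_pops=("derived1", "derived2"),
        effect_columns={"derived1": ("cis1", "trans1"), "derived2": ("cis2", "trans2")},
    )
    hybrids = {
        "cross1": simulate_hybrid_allele_counts(truth1, params, stream="hybrid1"),
        "cross2": simulate_hybrid_allele_counts(truth2, params, stream="hybrid2"),
    }
    lengths = simulate_transcript_lengths(params)
    return StudyDataset(
        params=params,
        truth={"cross1": truth1, "cross2": truth2},
        parental_counts=counts,
        sample_info=sample_info,
        hybrid_allele_counts=hybrids,
        transcript_lengths=lengths,
    )
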