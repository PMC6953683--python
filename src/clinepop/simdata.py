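"""Synthetic gradient populations with known truth.

Emulates a clinal sampling design: nine mangrove-coast populations spread along
a mean-annual-precipitation (BIO12) gradient from 1,300 to 6,000 mm, each with a
handful of genotyped individuals (2-13) and somewhat more phenotyped ones, ~15k
biallelic SNPs of which a small fraction are clinal, and heritable traits whose
between-population variance tracks the gradient.

Model
-----
* Neutral loci: population allele frequencies follow the Balding-Nichols model,
  ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency ``p``,
  so that E[p_k] = p and Var[p_k] = F p (1-p). ``F`` is the target
  differentiation level.
* Clinal loci: frequency is a deterministic logistic function of the
  standardized environment, ``p_k = logistic(slope * (z_k - mid))``.
* Genotypes: dosages are Binomial(2, p_k) per individual with independent
  per-call missingness.
* Traits: ``y_ij = mu + beta_env * z_j + b_j + e_ij`` with population effects
  ``b_j ~ N(0, sigma2_B)`` and residuals ``e_ij ~ N(0, sigma2_W)``.

Every simulated dataset carries a truth record (true F, clinal locus ids, the
population frequency matrix, variance components and population effects) so
that downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import child_rng
from .genio import (
    LOCUS_COLUMNS,
    GenotypeTable,
    read_env_table,
    read_pop_map,
    read_trait_table,
    read_vcf,
    write_pop_map,
    write_vcf,
)

__all__ = [
    "TraitParams",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pop_freqs",
    "simulate_genotypes",
    "simulate_traits",
    "generate_dataset",
    "TABLE1_BIO12",
    "TABLE1_N_GENO",
    "TABLE1_N_PHENO",
    "TABLE1_SALINITY",
    "TABLE1_COORDS",
]

# Sampling design of the study system: nine localities on the Pacific coast of
# Costa Rica, ordered dry/high-salinity -> wet/low-salinity.
TABLE1_BIO12 = (1300.0, 1500.0, 1500.0, 1700.0, 1700.0, 3200.0, 4000.0, 5900.0, 6000.0)
TABLE1_SALINITY = (55.0, 45.0, 45.0, 47.0, 41.0, 25.0, 17.0, 18.0, 19.0)
TABLE1_N_GENO = (5, 12, 3, 2, 13, 8, 9, 3, 13)
TABLE1_N_PHENO = (15, 20, 5, 3, 19, 16, 14, 5, 18)
TABLE1_COORDS = (  # (lat, lon)
    (10.77, -85.66), (10.81, -85.83), (10.15, -85.80), (10.08, -85.11),
    (10.06, -84.95), (9.78, -84.64), (8.88, -83.60), (8.69, -83.47),
    (8.64, -83.17),
)


@dataclasses.dataclass(frozen=True)
class TraitParams:
    """Parameters of one simulated trait (units of the trait; mm for lengths)."""

    trait_mu: float = 10.0
    sigma2_B: float = 0.04
    sigma2_W: float = 0.006
    beta_env: float = 0.0

    def validate(self) -> None:
        if self.sigma2_B < 0:
            raise ValueError("sigma2_B must be >= 0")
        if self.sigma2_W <= 0:
            raise ValueError("sigma2_W must be > 0")


@dataclasses.dataclass
class SimulationConfig:
    """Study-design and model parameters of one synthetic dataset.

    Defaults reproduce the clinal design: nine populations on the BIO12
    gradient with the genotyped/phenotyped sample sizes of the study system,
    ~15k SNPs with a small clinal fraction, weak differentiation (F = 0.015,
    the neutral multilocus theta regime of the system), and a single trait
    whose variance components default to the bill-height scale (sigma2_B =
    0.04 mm^2, sigma2_W = 0.006 mm^2).
    """

    n_pops: int = 9
    env: tuple[float, ...] = TABLE1_BIO12
    salinity: tuple[float, ...] = TABLE1_SALINITY
    coords: tuple[tuple[float, float], ...] = TABLE1_COORDS
    n_geno: tuple[int, ...] = TABLE1_N_GENO
    n_pheno: tuple[int, ...] = TABLE1_N_PHENO
    n_neutral: int = 15000
    n_clinal: int = 50
    F: float = 0.015
    cline_slope: float = 3.0
    cline_mid: float = 0.0
    traits: dict[str, TraitParams] = dataclasses.field(
        default_factory=lambda: {"trait": TraitParams()}
    )
    missing_rate: float = 0.05
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    loci_per_scaffold: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.env = tuple(float(v) for v in self.env)
        self.n_geno = tuple(int(v) for v in self.n_geno)
        self.n_pheno = tuple(int(v) for v in self.n_pheno)
        if not (len(self.env) == len(self.n_geno) == self.n_pops):
            raise ValueError("n_pops must equal len(env) and len(n_geno)")
        if len(self.n_pheno) != self.n_pops:
            raise ValueError("n_pheno must have one entry per population")
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.n_geno) < 0 or min(self.n_pheno) < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.n_neutral < 0 or self.n_clinal < 0:
            raise ValueError("locus counts must be non-negative")
        if isinstance(self.traits, dict):
            self.traits = {
                k: v if isinstance(v, TraitParams) else TraitParams(**v)
                for k, v in self.traits.items()
            }
        for tp in self.traits.values():
            tp.validate()

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    @property
    def z_env(self) -> np.ndarray:
        """Environment standardized to zero mean, unit SD across populations."""
        env = np.asarray(self.env, dtype=float)
        sd = env.std(ddof=0)
        if sd == 0:
            raise ValueError("environment is constant across populations")
        return (env - env.mean()) / sd

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclasses.dataclass
class SimulatedDataset:
    """Genotypes + traits + the truth record that generated them."""

    genotypes: GenotypeTable
    traits: pd.DataFrame
    env_table: pd.DataFrame
    truth: dict


def simulate_pop_freqs(
    p_anc: float,
    F: float,
    env: np.ndarray,
    clinal: bool = False,
    cline_slope: float = 3.0,
    cline_mid: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-population allele frequencies for one locus.

    Neutral loci draw from the Balding-Nichols Beta; clinal loci follow a
    logistic cline on the standardized environment ``env``.
    """
    if not 0.0 < p_anc < 1.0:
        raise ValueError("p_anc must lie in (0, 1)")
    if not 0.0 < F < 1.0:
        raise ValueError("F must lie in (0, 1)")
    env = np.asarray(env, dtype=float)
    if clinal:
        return 1.0 / (1.0 + np.exp(-cline_slope * (env - cline_mid)))
    rng = child_rng(seed, "popfreqs")
    ratio = (1.0 - F) / F
    return rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=env.shape)


def simulate_genotypes(
    freqs: np.ndarray,
    n_geno: tuple[int, ...] | list[int],
    missing_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    pop_names: list[str] | None = None,
    loci_per_scaffold: int = 200,
) -> GenotypeTable:
    """Draw Binomial(2, p) dosages from a pops x loci frequency matrix.

    Each call is independently set missing with probability ``missing_rate``.
    Loci get synthetic scaffold/position coordinates (``loci_per_scaffold``
    loci per scaffold, positions strictly increasing).
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if freqs.min() < 0 or freqs.max() > 1:
        raise ValueError("frequencies must lie in [0, 1]")
    n_geno = [int(n) for n in n_geno]
    if min(n_geno) < 0:
        raise ValueError("sample counts must be non-negative")
    if len(n_geno) != freqs.shape[0]:
        raise ValueError("one sample count per population is required")
    n_pops, n_loci = freqs.shape
    if pop_names is None:
        pop_names = [f"pop{i + 1}" for i in range(n_pops)]

    rng = child_rng(seed, "genotypes")
    samples: list[str] = []
    populations: dict[str, str] = {}
    blocks = []
    for k, (pop, n) in enumerate(zip(pop_names, n_geno)):
        ids = [f"{pop}_ind{i + 1}" for i in range(n)]
        samples.extend(ids)
        populations.update({s: pop for s in ids})
        blocks.append(rng.binomial(2, freqs[k], size=(n, n_loci)).astype(float))
    dosages = np.vstack(blocks) if blocks else np.empty((0, n_loci))
    if missing_rate > 0 and dosages.size:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan

    # synthetic coordinates: fixed 1 kb spacing keeps positions reproducible
    idx = np.arange(n_loci)
    scaf = idx // loci_per_scaffold + 1
    pos = (idx % loci_per_scaffold) * 1000 + 1
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_loci)]
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, n_loci)) % 4]
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{i + 1}" for i in idx],
            "scaffold": [f"scaffold{s}" for s in scaf],
            "position": pos,
            "ref": ref,
            "alt": alt,
        }
    )[LOCUS_COLUMNS]
    return GenotypeTable(samples, populations, loci, dosages)


def simulate_traits(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the per-individual trait table.

    Returns the trait table (sample_id, population, one column per trait) and
    a truth dict with the drawn population effects per trait. Traits are
    simulated independently of each other. Phenotyped samples include the
    genotyped ones (same ids) plus phenotype-only extras per population.
    """
    rng = child_rng(seed if seed is not None else config.seed, "traits")
    z = config.z_env
    rows: list[tuple[str, str]] = []
    for pop, n_g, n_p in zip(config.pop_names, config.n_geno, config.n_pheno):
        n_tot = max(n_g, n_p)
        for i in range(n_tot):
            name = (
                f"{pop}_ind{i + 1}" if i < n_g else f"{pop}_pheno{i - n_g + 1}"
            )
            rows.append((name, pop))
    df = pd.DataFrame(rows, columns=["sample_id", "population"])
    pop_of_row = df["population"].map(
        {p: k for k, p in enumerate(config.pop_names)}
    ).to_numpy()

    truth_effects: dict[str, list[float]] = {}
    for name, tp in config.traits.items():
        b = rng.normal(0.0, np.sqrt(tp.sigma2_B), size=config.n_pops)
        e = rng.normal(0.0, np.sqrt(tp.sigma2_W), size=len(df))
        df[name] = tp.trait_mu + tp.beta_env * z[pop_of_row] + b[pop_of_row] + e
        truth_effects[name] = b.tolist()
    return df, {"pop_effects": truth_effects}


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> SimulatedDataset:
    """Simulate a full dataset and (optionally) write it to disk.

    Writes ``genotypes.vcf``, ``pop_map.tsv``, ``environment.tsv``,
    ``traits.tsv`` and ``truth.json`` under ``outdir``. Output is byte-stable
    for a fixed config (including seed). Clinal loci are interleaved at random
    positions among the neutral ones and identified only in the truth record.
    """
    root = np.random.SeedSequence(config.seed)
    rng_freq, rng_geno, rng_place = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    z = config.z_env
    n_total = config.n_neutral + config.n_clinal

    lo, hi = config.ancestral_range
    p_anc = rng_freq.uniform(lo, hi, size=n_total)
    clinal_idx = np.sort(
        rng_place.choice(n_total, size=config.n_clinal, replace=False)
    )
    is_clinal = np.zeros(n_total, dtype=bool)
    is_clinal[clinal_idx] = True

    freqs = np.empty((config.n_pops, n_total))
    ratio = (1.0 - config.F) / config.F
    neutral = ~is_clinal
    n_neut = int(neutral.sum())
    freqs[:, neutral] = rng_freq.beta(
        p_anc[neutral] * ratio,
        (1.0 - p_anc[neutral]) * ratio,
        size=(config.n_pops, n_neut),
    )
    if config.n_clinal:
        cline = 1.0 / (
            1.0 + np.exp(-config.cline_slope * (z[:, None] - config.cline_mid))
        )
        freqs[:, is_clinal] = np.broadcast_to(cline, (config.n_pops, config.n_clinal))

    genotypes = simulate_genotypes(
        freqs,
        config.n_geno,
        missing_rate=config.missing_rate,
        seed=rng_geno,
        pop_names=config.pop_names,
        loci_per_scaffold=config.loci_per_scaffold,
    )
    traits, trait_truth = simulate_traits(config, seed=root.spawn(1)[0])

    env_table = pd.DataFrame(
        {
            "population": config.pop_names,
            "bio12": config.env,
            "salinity": config.salinity,
            "lon": [c[1] for c in config.coords],
            "lat": [c[0] for c in config.coords],
        }
    )
    truth = {
        "F": config.F,
        "clinal_loci": genotypes.loci["locus_id"].iloc[clinal_idx].tolist(),
        "pop_freqs": freqs.tolist(),
        "traits": {
            name: {
                "sigma2_B": tp.sigma2_B,
                "sigma2_W": tp.sigma2_W,
                "beta_env": tp.beta_env,
                "trait_mu": tp.trait_mu,
                "pop_effects": trait_truth["pop_effects"][name],
            }
            for name, tp in config.traits.items()
        },
        "seed": config.seed,
    }
    dataset = SimulatedDataset(genotypes, traits, env_table, truth)
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(dataset.genotypes, outdir / "genotypes.vcf")
    write_pop_map(dataset.genotypes.populations, outdir / "pop_map.tsv")
    # %.17g keeps float64 values bit-exact through the TSV round trip
    dataset.env_table.to_csv(
        outdir / "environment.tsv", sep="\t", index=False, float_format="%.17g"
    )
    dataset.traits.to_csv(
        outdir / "traits.tsv", sep="\t", index=False, float_format="%.17g"
    )
    (outdir / "truth.json").write_text(json.dumps(dataset.truth, indent=1))


def read_dataset(indir: str | Path) -> SimulatedDataset:
    """Re-read a written dataset; inverse of :func:`write_dataset`."""
    indir = Path(indir)
    pop_map = read_pop_map(indir / "pop_map.tsv")
    genotypes = read_vcf(indir / "genotypes.vcf", pop_map=pop_map)
    if isinstance(genotypes, tuple):  # pragma: no cover - we never write non-SNPs
        genotypes = genotypes[0]
    return SimulatedDataset(
        genotypes=genotypes,
        traits=read_trait_table(indir / "traits.tsv"),
        env_table=read_env_table(indir / "environment.tsv"),
        truth=json.loads((indir / "truth.json").read_text()),
    )
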