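"""Synthetic paired miRNA/mRNA experiments with known ground truth.

The generator emulates the data model the downstream pipeline assumes:

* negative-binomial counts with sample-specific log-normal library-size
  factors and gene-wise baselines drawn log-uniformly,
* planted differentially expressed genes and miRNAs with a fixed |log2FC|
  in a configurable two-group design,
* planted miRNA->target pairs whose log-scale latent abundances are
  anti-correlated at a configured population level, arranged so every planted
  target gene is shared by two planted miRNAs (the regime the shared-target
  filter selects for),
* prediction and validation tables with per-tool sensitivity and
  false-positive noise emulating an eight-tool target-prediction compendium
  and a validation database.

Anti-correlation is planted on latent log2 means through a per-module shared
factor: a module is two same-direction DE miRNAs plus their common target
genes; miRNAs load sqrt(c) on the module factor and each gene loads rho/sqrt(c)
(c = (1 + rho^2)/2), so every planted (miRNA, gene) pair has latent correlation
exactly rho within condition.  Because paired miRNAs and genes also shift in
opposite directions between conditions, the across-group log-scale correlation
is stronger in magnitude than rho; observed count correlations are attenuated
by counting noise.

All three generators are deterministic functions of the config: each draws
from its own numpy Generator seeded from (cfg.seed, stream offset), so adding
one generator call never perturbs another's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_paired_experiment",
    "simulate_prediction_db",
    "simulate_validation_db",
    "simulate_gene_sets",
    "paper_scale_config",
]

DEFAULT_TOOLS = (
    "diana-microt", "elmmo", "microcosm", "miranda", "mirdb", "pictar", "pita", "targetscan",
)


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the paired simulation.

    Defaults describe an adequately powered desk-scale study: 8 case vs 8
    control samples, 2000 genes / 200 miRNAs, 40 DE genes and 8 DE miRNAs at
    |log2FC| = 2, 16 planted regulatory pairs with latent correlation -0.9,
    an eight-tool prediction compendium at 95% per-tool sensitivity and 2%
    false-positive rate, and a fully covering validation database.  The
    in-study design (4 case vs 3 control) is available via
    :func:`paper_scale_config`.
    """

    n_case: int = 8
    n_control: int = 8
    n_genes: int = 2000
    n_mirnas: int = 200
    baseline_mean_log_range: tuple[float, float] = (1.0, 3.5)  # log10 of mean counts
    dispersion: float = 0.1  # NB alpha: var = mu + alpha*mu^2
    size_factor_log_sd: float = 0.2  # natural-log sd of library-size factors
    n_de_genes: int = 40
    n_de_mirnas: int = 8
    de_log2fc: float = 2.0
    n_true_pairs: int = 16
    pair_correlation: float = -0.9
    pair_latent_sd: float = 0.5  # log2-scale sd of the planted latent component
    tool_names: tuple[str, ...] = DEFAULT_TOOLS
    tool_sensitivity: float = 0.95
    tool_fp_rate: float = 0.02
    validated_fraction: float = 1.0
    validation_sources: tuple[str, ...] = ("mirtarbase", "tarbase")
    validation_contamination: int = 0  # spurious non-true pairs added to the validation table
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control) < 2:
            raise ConfigError("need >=2 samples per condition")
        if self.n_de_genes > self.n_genes or self.n_de_mirnas > self.n_mirnas:
            raise ConfigError("more DE features requested than features simulated")
        if self.n_true_pairs > self.n_de_mirnas * self.n_de_genes:
            raise ConfigError("n_true_pairs exceeds n_de_mirnas * n_de_genes")
        if self.n_true_pairs > 0 and self.n_de_mirnas < 2:
            raise ConfigError("planted pairs require at least 2 DE miRNAs (shared targets)")
        if not (-1.0 < self.pair_correlation < 0.0):
            raise ConfigError("pair_correlation must lie in (-1, 0)")
        for name in ("tool_sensitivity", "tool_fp_rate", "validated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0 or self.size_factor_log_sd < 0 or self.pair_latent_sd < 0:
            raise ConfigError("dispersion, size_factor_log_sd and pair_latent_sd must be >= 0")
        lo, hi = self.baseline_mean_log_range
        if hi < lo:
            raise ConfigError("baseline_mean_log_range must be (low, high)")
        if self.de_log2fc <= 0:
            raise ConfigError("de_log2fc must be > 0")
        if len(set(self.tool_names)) != len(self.tool_names):
            raise ConfigError("tool names must be unique")


def paper_scale_config(**overrides) -> SimulationConfig:
    """The in-study design scale: 4 case vs 3 control.  Illustration only —
    recovery statistics at this depth are underpowered by construction."""
    base = dict(n_case=4, n_control=3)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticTruth:
    """Planted ground truth: signed DE features and the planted regulatory pairs."""

    de_genes: dict[str, float]  # gene -> planted log2FC (case vs control)
    de_mirnas: dict[str, float]
    true_pairs: list[tuple[str, str]]  # (mirna, gene)
    pair_correlation: float

    def __post_init__(self):
        genes = set(self.de_genes)
        mirnas = set(self.de_mirnas)
        for m, g in self.true_pairs:
            if m not in mirnas or g not in genes:
                raise ConfigError(f"true pair ({m}, {g}) not within planted DE features")
            if self.de_mirnas[m] * self.de_genes[g] >= 0:
                raise ConfigError(f"true pair ({m}, {g}) members must have opposite DE signs")

    @property
    def true_pair_set(self) -> set[tuple[str, str]]:
        return set(self.true_pairs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "de_genes": self.de_genes,
                    "de_mirnas": self.de_mirnas,
                    "true_pairs": [list(p) for p in self.true_pairs],
                    "pair_correlation": self.pair_correlation,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            de_genes=raw["de_genes"],
            de_mirnas=raw["de_mirnas"],
            true_pairs=[tuple(p) for p in raw["true_pairs"]],
            pair_correlation=raw["pair_correlation"],
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha*mu^2 (Poisson when alpha == 0)."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def _plan_pairs(
    cfg: SimulationConfig, gene_ids: list[str], mirna_ids: list[str], rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float], list[tuple[str, str]], list[dict]]:
    """Choose DE features, signs and the module structure of planted pairs.

    Returns (de_genes, de_mirnas, true_pairs, modules); each module is a dict
    with keys mirnas (2 ids) and genes (its shared target genes).
    """
    de_gene_ids = list(rng.choice(gene_ids, size=cfg.n_de_genes, replace=False))
    de_mirna_ids = list(rng.choice(mirna_ids, size=cfg.n_de_mirnas, replace=False))
    lfc = cfg.de_log2fc
    # alternate signs so both directions exist whenever >=2 features are planted
    mirna_signs = {m: (1.0 if i % 2 == 0 else -1.0) for i, m in enumerate(de_mirna_ids)}

    n_pair_genes = (cfg.n_true_pairs + 1) // 2
    if n_pair_genes > cfg.n_de_genes:
        raise ConfigError("n_true_pairs requires more DE genes than configured")
    pair_genes = de_gene_ids[:n_pair_genes]

    # modules: disjoint same-sign miRNA duos; genes assigned round-robin
    up = [m for m in de_mirna_ids if mirna_signs[m] > 0]
    down = [m for m in de_mirna_ids if mirna_signs[m] < 0]
    duos = [up[i : i + 2] for i in range(0, len(up) - 1, 2)]
    duos += [down[i : i + 2] for i in range(0, len(down) - 1, 2)]
    if cfg.n_true_pairs > 0 and not duos:
        raise ConfigError("planted pairs require at least one same-direction miRNA duo")
    modules = [{"mirnas": duo, "genes": []} for duo in duos]

    gene_signs: dict[str, float] = {}
    true_pairs: list[tuple[str, str]] = []
    budget = cfg.n_true_pairs
    for i, g in enumerate(pair_genes):
        mod = modules[i % len(modules)]
        gene_signs[g] = -mirna_signs[mod["mirnas"][0]]
        mod["genes"].append(g)
        for m in mod["mirnas"]:
            if budget > 0:
                true_pairs.append((m, g))
                budget -= 1
    # non-pair DE genes get random signs
    for g in de_gene_ids[n_pair_genes:]:
        gene_signs[g] = 1.0 if rng.random() < 0.5 else -1.0

    de_genes = {g: s * lfc for g, s in gene_signs.items()}
    de_mirnas = {m: s * lfc for m, s in mirna_signs.items()}
    modules = [m for m in modules if m["genes"]]
    return de_genes, de_mirnas, true_pairs, modules


def simulate_paired_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, SampleTable, SyntheticTruth]:
    """Simulate paired mRNA and miRNA count matrices with planted structure.

    Counts for feature f in sample j are NB with mean
    ``s_j * q_f * 2**(beta_f * x_j + z_fj)`` and dispersion alpha, where x_j is
    the case indicator, beta_f the planted log2FC (0 for null features) and
    z_fj the latent module component (0 for features outside planted pairs).
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_case + cfg.n_control
    x = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)
    sample_ids = [f"case{i+1:02d}" for i in range(cfg.n_case)] + [
        f"ctrl{i+1:02d}" for i in range(cfg.n_control)
    ]
    samples = SampleTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "condition": ["case"] * cfg.n_case + ["control"] * cfg.n_control}
        )
    )
    gene_ids = [f"GENE{i+1:05d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"sim-miR-{i+1:04d}" for i in range(cfg.n_mirnas)]

    de_genes, de_mirnas, true_pairs, modules = _plan_pairs(cfg, gene_ids, mirna_ids, rng)

    lo, hi = cfg.baseline_mean_log_range
    q_gene = 10 ** rng.uniform(lo, hi, size=cfg.n_genes)
    q_mirna = 10 ** rng.uniform(lo, hi, size=cfg.n_mirnas)
    sf_gene = np.exp(rng.normal(0.0, cfg.size_factor_log_sd, size=n))
    sf_mirna = np.exp(rng.normal(0.0, cfg.size_factor_log_sd, size=n))

    beta_gene = np.array([de_genes.get(g, 0.0) for g in gene_ids])
    beta_mirna = np.array([de_mirnas.get(m, 0.0) for m in mirna_ids])

    z_gene = np.zeros((cfg.n_genes, n))
    z_mirna = np.zeros((cfg.n_mirnas, n))
    rho = cfg.pair_correlation
    c = (1.0 + rho**2) / 2.0  # shared-factor loading^2 for the miRNA duo
    g_index = {g: i for i, g in enumerate(gene_ids)}
    m_index = {m: i for i, m in enumerate(mirna_ids)}
    for mod in modules:
        u = rng.normal(0.0, 1.0, size=n)
        for m in mod["mirnas"]:
            e = rng.normal(0.0, 1.0, size=n)
            z_mirna[m_index[m]] = cfg.pair_latent_sd * (np.sqrt(c) * u + np.sqrt(1 - c) * e)
        for g in mod["genes"]:
            e = rng.normal(0.0, 1.0, size=n)
            load = rho / np.sqrt(c)
            z_gene[g_index[g]] = cfg.pair_latent_sd * (load * u + np.sqrt(1 - load**2) * e)

    mu_gene = sf_gene[None, :] * q_gene[:, None] * 2 ** (beta_gene[:, None] * x[None, :] + z_gene)
    mu_mirna = sf_mirna[None, :] * q_mirna[:, None] * 2 ** (beta_mirna[:, None] * x[None, :] + z_mirna)
    counts_gene = _nb_draw(rng, mu_gene, cfg.dispersion)
    counts_mirna = _nb_draw(rng, mu_mirna, cfg.dispersion)

    mrna = CountMatrix(
        pd.DataFrame(counts_gene, index=gene_ids, columns=sample_ids),
        meta={"baseline_mean": dict(zip(gene_ids, q_gene)), "size_factors": dict(zip(sample_ids, sf_gene))},
    )
    mirna = CountMatrix(
        pd.DataFrame(counts_mirna, index=mirna_ids, columns=sample_ids),
        meta={"baseline_mean": dict(zip(mirna_ids, q_mirna)), "size_factors": dict(zip(sample_ids, sf_mirna))},
    )
    truth = SyntheticTruth(
        de_genes=de_genes, de_mirnas=de_mirnas, true_pairs=true_pairs,
        pair_correlation=rho,
    )
    return mrna, mirna, samples, truth


def _all_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    return (
        [f"GENE{i+1:05d}" for i in range(cfg.n_genes)],
        [f"sim-miR-{i+1:04d}" for i in range(cfg.n_mirnas)],
    )


def simulate_prediction_db(truth: SyntheticTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Per-tool target predictions: each true pair is listed by each tool with
    probability ``tool_sensitivity``; each non-true (miRNA, gene) combination
    with probability ``tool_fp_rate``.  Columns (mirna, gene, tool)."""
    cfg.validate()
    rng = _rng(cfg, 1)
    tools = list(cfg.tool_names)
    gene_ids, mirna_ids = _all_ids(cfg)
    rows: list[tuple[str, str, str]] = []

    pairs = truth.true_pairs
    hit = rng.random((len(pairs), len(tools))) < cfg.tool_sensitivity
    for (m, g), row in zip(pairs, hit):
        rows.extend((m, g, t) for t, h in zip(tools, row) if h)

    if cfg.tool_fp_rate > 0:
        n_combo = cfg.n_mirnas * cfg.n_genes
        true_idx = np.sort(
            np.array(
                [mirna_ids.index(m) * cfg.n_genes + gene_ids.index(g) for m, g in pairs],
                dtype=np.int64,
            )
        )
        n_nontrue = n_combo - len(true_idx)
        for t in tools:
            k = rng.binomial(n_nontrue, cfg.tool_fp_rate)
            picked = rng.choice(n_nontrue, size=k, replace=False)
            # map indices over the gap left by true combos
            picked = picked + np.searchsorted(true_idx - np.arange(len(true_idx)), picked, side="right")
            for idx in np.sort(picked):
                rows.append((mirna_ids[idx // cfg.n_genes], gene_ids[idx % cfg.n_genes], t))

    return pd.DataFrame(rows, columns=["mirna", "gene", "tool"])


def simulate_validation_db(truth: SyntheticTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Validation records: each true pair is included with probability
    ``validated_fraction`` under a random source; ``validation_contamination``
    spurious non-true pairs are added.  Columns (mirna, gene, source)."""
    cfg.validate()
    rng = _rng(cfg, 2)
    sources = list(cfg.validation_sources)
    rows: list[tuple[str, str, str]] = []
    for m, g in truth.true_pairs:
        if rng.random() < cfg.validated_fraction:
            rows.append((m, g, sources[rng.integers(len(sources))]))
    gene_ids, mirna_ids = _all_ids(cfg)
    true_set = truth.true_pair_set
    added = 0
    while added < cfg.validation_contamination:
        m = mirna_ids[rng.integers(len(mirna_ids))]
        g = gene_ids[rng.integers(len(gene_ids))]
        if (m, g) not in true_set:
            rows.append((m, g, sources[rng.integers(len(sources))]))
            added += 1
    return pd.DataFrame(rows, columns=["mirna", "gene", "source"])


def simulate_gene_sets(
    cfg: SimulationConfig, n_sets: int = 50, size_range: tuple[int, int] = (10, 50)
):
    """Random gene-set collection over the simulated gene universe (for ORA)."""
    from .io import GeneSetCollection

    rng = _rng(cfg, 3)
    gene_ids, _ = _all_ids(cfg)
    sets, descriptions = {}, {}
    lo, hi = size_range
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{i+1:03d}"
        sets[name] = set(rng.choice(gene_ids, size=size, replace=False))
        descriptions[name] = f"random synthetic gene set {i+1}"
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=set(gene_ids))


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["baseline_mean_log_range"] = list(d["baseline_mean_log_range"])
    d["tool_names"] = list(d["tool_names"])
    d["validation_sources"] = list(d["validation_sources"])
    return d
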