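"""Synthetic data with the statistical structure of the imaging-genetics SEM.

Genotypes are drawn under Hardy-Weinberg equilibrium with minor-allele
frequencies from Beta(1, 2); latent variables are linear combinations of
the centred genotypes plus Gaussian noise; region measurements load on
their group's latent with Uniform(0.5, 1.5) weights plus Gaussian noise;
and a binary phenotype follows a logistic model on a subset of the latents
with weights of +-10. The defaults generate 100-individual-scale study
replicates: 500 individuals, 20 SNPs, five region groups of sizes
20/10/10/5/5 (50 regions), 10 nonzero SNP-to-latent weights of +-1, noise
standard deviation 2 on both layers, and two phenotype-linked latents.

Robustness variants cover wider noise levels, different numbers of nonzero
SNP weights, and misspecified region groupings produced by swapping
region-group links.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SEMSpec, build_spec


class SimulationError(ValueError):
    """Invalid simulation configuration or infeasible request."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one synthetic-study condition.

    Defaults correspond to the base condition of the simulation study;
    the robustness sweeps vary ``latent_noise_sd`` / ``region_noise_sd``
    over 1..5, ``n_nonzero_a`` over 2..20, and ``n_swaps`` >= 1.
    """

    n_individuals: int = 500
    n_snps: int = 20
    group_sizes: tuple = (20, 10, 10, 5, 5)
    maf_beta_shapes: tuple = (1.0, 2.0)
    n_nonzero_a: int = 10
    a_weight: float = 1.0
    loading_range: tuple = (0.5, 1.5)
    latent_noise_sd: float = 2.0
    region_noise_sd: float = 2.0
    n_phenotype_latents: int = 2
    phenotype_weight: float = 10.0
    phenotype_intercept: float = 0.0
    n_swaps: int = 0
    seed: int | None = None

    def __post_init__(self):
        m = len(self.group_sizes)
        if any(s < 2 for s in self.group_sizes):
            raise SimulationError("each region group needs at least 2 regions")
        if not (0 <= self.n_nonzero_a <= m * self.n_snps):
            raise SimulationError("n_nonzero_a exceeds the m x p weight grid")
        if not (0 <= self.n_phenotype_latents <= m):
            raise SimulationError("n_phenotype_latents exceeds the latent count")
        if self.latent_noise_sd <= 0 or self.region_noise_sd <= 0:
            raise SimulationError("noise standard deviations must be positive")
        if min(self.maf_beta_shapes) <= 0:
            raise SimulationError("beta shape parameters must be positive")

    @property
    def m(self) -> int:
        return len(self.group_sizes)

    @property
    def q(self) -> int:
        return int(sum(self.group_sizes))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedDataset:
    """One synthetic replicate plus its generating truth."""

    g: np.ndarray                 # n x p genotypes, 0/1/2
    z_true: np.ndarray            # n x m latent values
    x: np.ndarray                 # n x q region measurements
    y: np.ndarray                 # n binary phenotype
    a_true: np.ndarray            # m x p SNP -> latent weights
    b_true: np.ndarray            # q x m loadings (block structured)
    phenotype_weights: np.ndarray  # m latent -> phenotype weights
    mafs: np.ndarray              # p minor-allele frequencies
    true_effect_snps: frozenset   # SNPs on a phenotype-linked latent
    spec: SEMSpec
    config: SimulationConfig

    def true_effect_mask(self) -> np.ndarray:
        mask = np.zeros(self.config.n_snps, dtype=bool)
        mask[list(self.true_effect_snps)] = True
        return mask

    def write_tables(self, directory) -> dict:
        """Write the dataset as the CSV/TSV tables the pipeline reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        samples = [f"S{i+1:04d}" for i in range(len(self.y))]
        paths = {
            "genotypes": directory / "genotypes.csv",
            "regions": directory / "regions.csv",
            "phenotype": directory / "phenotype.csv",
            "grouping": directory / "grouping.tsv",
            "truth": directory / "truth.json",
        }
        pd.DataFrame(self.g, index=samples, columns=self.spec.snp_ids).to_csv(
            paths["genotypes"], index_label="sample_id"
        )
        pd.DataFrame(self.x, index=samples, columns=self.spec.region_ids).to_csv(
            paths["regions"], index_label="sample_id"
        )
        pd.DataFrame({"phenotype": self.y}, index=samples).to_csv(
            paths["phenotype"], index_label="sample_id"
        )
        pd.DataFrame(
            {
                "region_id": self.spec.region_ids,
                "group_code": [self.spec.membership[r] for r in self.spec.region_ids],
            }
        ).to_csv(paths["grouping"], sep="\t", index=False)
        truth = {
            "a_true": self.a_true.tolist(),
            "b_true": self.b_true.tolist(),
            "phenotype_weights": self.phenotype_weights.tolist(),
            "mafs": self.mafs.tolist(),
            "true_effect_snps": sorted(self.true_effect_snps),
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def simulate_genotypes(
    n: int,
    p: int,
    beta_shapes: tuple = (1.0, 2.0),
    seed=None,
    mafs: np.ndarray | None = None,
):
    """Hardy-Weinberg genotypes with Beta-distributed allele frequencies.

    Per SNP a minor-allele frequency f is drawn from Beta(*beta_shapes*)
    (default Beta(1, 2), mean 1/3) and genotypes are i.i.d. with
    P(0) = (1-f)^2, P(1) = 2f(1-f), P(2) = f^2. Pass ``mafs`` to fix the
    frequencies instead of drawing them.

    Returns
    -------
    (g, mafs) : (n x p int array, length-p float array)
    """
    if n < 1 or p < 0:
        raise SimulationError("need n >= 1 and p >= 0")
    a, b = beta_shapes
    if a <= 0 or b <= 0:
        raise SimulationError("beta shape parameters must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.beta(a, b, size=p)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (p,) or np.any((mafs < 0) | (mafs > 1)):
            raise SimulationError("mafs must be p frequencies in [0, 1]")
    g = rng.binomial(2, mafs[np.newaxis, :], size=(n, p))
    return g, mafs


def default_spec(config: SimulationConfig) -> SEMSpec:
    """The (true) model spec implied by a configuration's group sizes."""
    region_ids, groups = [], {}
    r = 0
    for gi, size in enumerate(config.group_sizes):
        code = f"G{gi + 1}"
        for _ in range(size):
            rid = f"R{r + 1:03d}"
            region_ids.append(rid)
            groups[rid] = code
            r += 1
    snp_ids = [f"snp{j + 1:02d}" for j in range(config.n_snps)]
    return build_spec(groups, snp_ids=snp_ids, region_order=region_ids)


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Draw one complete replicate (genotypes, latents, regions, phenotype).

    The latents are driven by the *centred* genotypes, matching the
    zero-mean convention of the model equations; regions are generated on
    their natural scale and left for the preprocessing step to centre and
    scale.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p, m, q = config.n_individuals, config.n_snps, config.m, config.q

    g, mafs = simulate_genotypes(n, p, config.maf_beta_shapes, seed=rng)
    g_c = g - g.mean(axis=0)

    a_true = np.zeros((m, p))
    if config.n_nonzero_a:
        flat = rng.choice(m * p, size=config.n_nonzero_a, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_nonzero_a)
        a_true.flat[flat] = signs * config.a_weight

    spec = default_spec(config)
    lo, hi = config.loading_range
    b_true = np.zeros((q, m))
    gidx = spec.group_index
    b_true[np.arange(q), gidx] = rng.uniform(lo, hi, size=q)

    z = g_c @ a_true.T + rng.normal(scale=config.latent_noise_sd, size=(n, m))
    x = z @ b_true.T + rng.normal(scale=config.region_noise_sd, size=(n, q))

    w = np.zeros(m)
    if config.n_phenotype_latents:
        which = rng.choice(m, size=config.n_phenotype_latents, replace=False)
        w[which] = rng.choice([-1.0, 1.0], size=config.n_phenotype_latents)
        w *= config.phenotype_weight
    eta = config.phenotype_intercept + z @ w
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))

    linked = np.abs(w) > 0
    true_effect = frozenset(int(j) for j in np.where(np.any(a_true[linked] != 0, axis=0))[0])
    return SimulatedDataset(
        g=g, z_true=z, x=x, y=y, a_true=a_true, b_true=b_true,
        phenotype_weights=w, mafs=mafs, true_effect_snps=true_effect,
        spec=spec, config=config,
    )


def swap_region_links(spec: SEMSpec, n_swaps: int, seed=None) -> SEMSpec:
    """Misspecify a grouping by exchanging regions between group pairs.

    Each swap picks two distinct groups and moves one region from each to
    the other, so group sizes are preserved and every swap misspecifies
    exactly two region-group links. A region that has already been moved is
    never moved again, so no link is ever restored; if too few unmoved
    regions remain the request is rejected.
    """
    if n_swaps == 0:
        return spec
    if n_swaps < 0:
        raise SimulationError("n_swaps must be nonnegative")
    if spec.m < 2:
        raise SimulationError("swapping needs at least two groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    membership = dict(spec.membership)
    eligible = {g: list(spec.members(g)) for g in spec.group_ids}
    for _ in range(n_swaps):
        pairs = [
            (a, b)
            for i, a in enumerate(spec.group_ids)
            for b in spec.group_ids[i + 1:]
            if eligible[a] and eligible[b]
        ]
        if not pairs:
            raise SimulationError(
                f"cannot perform {n_swaps} swaps without returning a region "
                "to its original group"
            )
        a, b = pairs[rng.integers(len(pairs))]
        ra = eligible[a].pop(rng.integers(len(eligible[a])))
        rb = eligible[b].pop(rng.integers(len(eligible[b])))
        membership[ra], membership[rb] = b, a
    return build_spec(membership, snp_ids=spec.snp_ids, region_order=spec.region_ids)


def hwe_exact_test(genotype_counts) -> float:
    """Exact Hardy-Weinberg equilibrium test for one biallelic SNP.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa) — homozygous common,
    heterozygous, homozygous rare. The p value sums the conditional
    probabilities (given the allele counts) of all heterozygote counts no
    more probable than the observed one, the standard exact HWE test.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in genotype_counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise SimulationError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise SimulationError("no genotypes supplied")
    n_rare = 2 * n_hom2 + n_het
    if n_rare > n:  # orient so "rare" is the minor allele
        n_rare = 2 * n - n_rare

    from scipy.special import gammaln

    # het counts with the parity of the minor-allele count; conditional
    # pmf P(h) ∝ 2^h / (h! hom_rare! hom_common!)  (n! and allele-count
    # factorials are constant given the margins)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = hets * np.log(2.0) - gammaln(hets + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_prob = float(prob[hets == n_het][0])
    return float(prob[prob <= obs_prob * (1 + 1e-12)].sum())
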