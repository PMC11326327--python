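"""Forward simulation of two-generation genotyped sibling cohorts.

The generative model produces parents, mates them (optionally assortatively),
transmits genotypes to two or more offspring per family by Mendelian
segregation, and builds an education phenotype plus continuous and binary
mental-health outcomes with switchable bias channels:

* **dynastic effects / genetic nurture** — the mid-parent polygenic score
  enters the child's education (``eta``) and the outcome (``lambda_``)
  directly, violating the instrumental-variable independence assumption at
  the population level while remaining family-constant (and hence removable
  by a family fixed effect);
* **assortative mating** — spouses are rank-matched on an education-propensity
  phenotype to a target correlation ``rho_am``;
* **population structure** — two subpopulations with shifted allele
  frequencies and mean offsets on education and outcome;
* **classical confounding** — a shared family confounder loading on both
  education and outcome.

With every channel switched off, a downstream two-stage least squares fit of
the outcome on education, instrumented by the polygenic score, recovers the
causal effect ``theta``; this parameter-recovery property is the module's
reason to exist.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "ParentPool",
    "MatePairs",
    "simulate_parent_pool",
    "pair_mates",
    "transmit_genotypes",
    "generate_phenotypes",
    "simulate_cohort",
    "inject_missingness",
    "variant_info",
    "true_weight_table",
    "write_cohort",
    "read_cohort",
]

#: columns that carry simulation-only ground truth, never used by estimators
TRUTH_COLUMNS = ("_confounder", "_score_child", "_score_midparent")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the sibling-cohort generative model.

    Effect scales are on the standardized (SD-unit) scale: phenotypes are
    built as linear combinations of unit-variance components, with residual
    noise sized so the total variance is ~1 before standardization.  In
    particular, with all bias channels off, ``delta**2`` is the expected
    variance in education explained by the polygenic score (the paper-scale
    figure is 2–6%, so the default ``delta = sqrt(0.03)``).
    """

    n_families: int = 5000
    n_snps: int = 50
    #: either a fixed sibship size (>=2) or a {size: probability} mixture
    offspring_per_family: int | dict[int, float] = 2
    maf_range: tuple[float, float] = (0.1, 0.5)
    #: true causal effect of standardized education on the standardized outcome
    theta: float = -0.2
    #: direct genetic effect of the child's own score on education
    delta: float = 0.1732
    #: genetic-nurture (dynastic) effect of the mid-parent score on education
    eta: float = 0.0
    #: dynastic effect of the mid-parent score directly on the outcome
    lambda_: float = 0.0
    #: target spousal correlation of the mating phenotype, in [0, 1)
    rho_am: float = 0.0
    #: fraction of families belonging to subpopulation 2
    f_pop2: float = 0.0
    #: allele-frequency divergence magnitude between subpopulations
    fst_like_shift: float = 0.0
    pop_shift_edu: float = 0.0
    pop_shift_out: float = 0.0
    #: loadings of a shared family confounder on education / outcome
    conf_edu: float = 0.0
    conf_out: float = 0.0
    #: target prevalence of the binary outcome (liability-threshold model)
    prev_binary: float = 0.085
    #: per-SNP weights: "equal" or "gaussian" (|N(0,1)| draws)
    weight_mode: str = "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_snps < 1:
            raise ValueError("n_families and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must be within (0, 1), got {self.maf_range}")
        if not (0.0 < self.prev_binary < 1.0):
            raise ValueError("prev_binary must lie in (0, 1)")
        if not (0.0 <= self.rho_am < 1.0):
            raise ValueError("rho_am must lie in [0, 1)")
        if not (0.0 <= self.f_pop2 <= 1.0):
            raise ValueError("f_pop2 must lie in [0, 1]")
        if isinstance(self.offspring_per_family, dict):
            sizes = self.offspring_per_family
            if any(k < 2 for k in sizes) or abs(sum(sizes.values()) - 1.0) > 1e-9:
                raise ValueError("sibship-size mixture needs sizes >=2, probs summing to 1")
        elif self.offspring_per_family < 2:
            raise ValueError("offspring_per_family must be >= 2")
        for name in ("theta", "delta", "eta", "lambda_", "fst_like_shift",
                     "pop_shift_edu", "pop_shift_out", "conf_edu", "conf_out"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.weight_mode not in ("equal", "gaussian"):
            raise ValueError("weight_mode must be 'equal' or 'gaussian'")


@dataclass
class ParentPool:
    """Unpaired parents: genotypes, subpopulation labels, latent scores."""

    genotypes: np.ndarray          # (2*n_families, n_snps) int8
    subpop: np.ndarray             # (2*n_families,) in {1, 2}
    weights: np.ndarray            # (n_snps,) per-allele score weights
    freq_pop1: np.ndarray          # generating allele frequencies, subpop 1
    freq_pop2: np.ndarray          # generating allele frequencies, subpop 2
    score: np.ndarray = field(init=False)          # raw weighted dosage sum
    mating_phenotype: np.ndarray = field(init=False)

    def finalize(self, delta: float, rng: np.random.Generator) -> "ParentPool":
        self.score = self.genotypes @ self.weights
        s = _standardize(self.score)
        # the mating phenotype is the parent's own education propensity:
        # genetic part scaled by delta plus environmental noise
        noise_sd = np.sqrt(max(1.0 - delta**2, 0.05))
        self.mating_phenotype = delta * s + noise_sd * rng.standard_normal(s.size)
        return self


@dataclass
class MatePairs:
    """Mated couples, one row per family."""

    father_genotypes: np.ndarray   # (n_families, n_snps)
    mother_genotypes: np.ndarray
    father_score: np.ndarray       # raw weighted scores
    mother_score: np.ndarray
    father_phenotype: np.ndarray   # mating phenotype
    mother_phenotype: np.ndarray
    subpop: np.ndarray             # family subpopulation, in {1, 2}
    weights: np.ndarray

    @property
    def n_families(self) -> int:
        return self.father_genotypes.shape[0]

    def spousal_correlation(self) -> float:
        return float(np.corrcoef(self.father_phenotype, self.mother_phenotype)[0, 1])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def variant_info(n_snps: int) -> pd.DataFrame:
    """Variant metadata for a simulated cohort.

    Dosages count copies of the effect allele ``A``; the other allele is
    ``G`` (non-palindromic by construction).
    """
    return pd.DataFrame(
        {
            "variant_id": [f"rs{j:05d}" for j in range(n_snps)],
            "effect_allele": "A",
            "other_allele": "G",
            "column": [f"g_{j:04d}" for j in range(n_snps)],
        }
    )


def _snp_weights(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.weight_mode == "equal":
        return np.ones(params.n_snps)
    return np.abs(rng.standard_normal(params.n_snps))


def true_weight_table(params: SimParams) -> pd.DataFrame:
    """The generating per-variant weights, in score-file layout.

    Reconstructs the weights from ``params.seed`` by replaying the same RNG
    stream the simulation uses, so downstream polygenic-score construction
    can use the true instrument weights.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    info = variant_info(params.n_snps)
    return pd.DataFrame(
        {
            "variant_id": info["variant_id"],
            "effect_allele": info["effect_allele"],
            "other_allele": info["other_allele"],
            "weight": _snp_weights(params, rng),
        }
    )


def simulate_parent_pool(params: SimParams,
                         rng: np.random.Generator | None = None) -> ParentPool:
    """Draw 2·n_families parents with subpopulation-specific allele frequencies.

    Subpopulation 2 frequencies are shifted by ``fst_like_shift`` with
    alternating sign across SNPs and clamped to [0.05, 0.95].
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    m = params.n_snps
    weights = _snp_weights(params, rng)
    p1 = rng.uniform(*params.maf_range, size=m)
    sign = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    p2 = np.clip(p1 + params.fst_like_shift * sign, 0.05, 0.95)
    if np.any((p1 <= 0) | (p1 >= 1)):
        raise ValueError("allele frequencies escaped (0, 1)")

    n_fam2 = int(round(params.f_pop2 * params.n_families))
    fam_subpop = np.ones(params.n_families, dtype=np.int8)
    fam_subpop[:n_fam2] = 2
    parent_subpop = np.repeat(fam_subpop, 2)

    freqs = np.where(parent_subpop[:, None] == 2, p2[None, :], p1[None, :])
    genotypes = rng.binomial(2, freqs).astype(np.int8)
    pool = ParentPool(genotypes, parent_subpop, weights, p1, p2)
    return pool.finalize(params.delta, rng)


def pair_mates(pool: ParentPool, rho_am: float,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> MatePairs:
    """Mate parents within subpopulation by noisy rank-matching.

    One half of each subpopulation's parents acts as fathers, the other as
    mothers.  Fathers are sorted on their mating phenotype and matched to
    mothers sorted on a noised copy of theirs; the noise standard deviation
    solves ``corr(m, m + e) = rho_am``, so the realized spousal correlation
    approaches ``rho_am`` for large cohorts.  ``rho_am = 0`` is pure random
    pairing.
    """
    if not (0.0 <= rho_am < 1.0):
        raise ValueError("rho_am must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = pool.genotypes.shape[0]
    if n % 2:
        raise ValueError("parent pool size must be even")

    fg, mg, fs, ms, fp, mp, sp = [], [], [], [], [], [], []
    for pop in np.unique(pool.subpop):
        idx = np.flatnonzero(pool.subpop == pop)
        idx = rng.permutation(idx)
        half = idx.size // 2
        fathers, mothers = idx[:half], idx[half:2 * half]
        ph_f = pool.mating_phenotype[fathers]
        ph_m = pool.mating_phenotype[mothers]
        if rho_am == 0.0:
            order_f = np.arange(half)
            order_m = np.arange(half)
        else:
            sd = ph_m.std()
            noise_sd = sd * np.sqrt(1.0 / rho_am**2 - 1.0)
            order_f = np.argsort(ph_f, kind="stable")
            order_m = np.argsort(ph_m + noise_sd * rng.standard_normal(half),
                                 kind="stable")
        fathers, mothers = fathers[order_f], mothers[order_m]
        fg.append(pool.genotypes[fathers]); mg.append(pool.genotypes[mothers])
        fs.append(pool.score[fathers]); ms.append(pool.score[mothers])
        fp.append(pool.mating_phenotype[fathers]); mp.append(pool.mating_phenotype[mothers])
        sp.append(np.full(half, pop, dtype=np.int8))

    return MatePairs(
        np.concatenate(fg), np.concatenate(mg),
        np.concatenate(fs), np.concatenate(ms),
        np.concatenate(fp), np.concatenate(mp),
        np.concatenate(sp), pool.weights,
    )


def _sibship_sizes(params: SimParams, n_families: int,
                   rng: np.random.Generator) -> np.ndarray:
    spec = params.offspring_per_family
    if isinstance(spec, dict):
        sizes = np.array(sorted(spec), dtype=int)
        probs = np.array([spec[s] for s in sizes], dtype=float)
        return rng.choice(sizes, size=n_families, p=probs)
    return np.full(n_families, int(spec), dtype=int)


def transmit_genotypes(pairs: MatePairs,
                       offspring_per_family: int | dict[int, float] | np.ndarray = 2,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mendelian transmission: each offspring allele is an independent
    Bernoulli(g/2) draw per parent.

    Returns ``(genotypes, family_index)`` with one row per offspring; siblings
    share a ``family_index`` row in ``pairs``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(offspring_per_family, np.ndarray):
        sizes = offspring_per_family.astype(int)
    elif isinstance(offspring_per_family, dict):
        sizes = _sibship_sizes(
            SimParams(offspring_per_family=offspring_per_family), pairs.n_families, rng
        )
    else:
        if int(offspring_per_family) < 2:
            raise ValueError("offspring_per_family must be >= 2")
        sizes = np.full(pairs.n_families, int(offspring_per_family), dtype=int)

    fam_idx = np.repeat(np.arange(pairs.n_families), sizes)
    pf = pairs.father_genotypes[fam_idx] / 2.0
    pm = pairs.mother_genotypes[fam_idx] / 2.0
    genotypes = (rng.binomial(1, pf) + rng.binomial(1, pm)).astype(np.int8)
    return genotypes, fam_idx


def generate_phenotypes(genotypes: np.ndarray, fam_idx: np.ndarray,
                        pairs: MatePairs, params: SimParams,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Build education, a continuous outcome and a liability-threshold binary
    outcome on the offspring generation.

    Education:   ``delta·S_child + eta·S_midparent + conf_edu·C + pop shift + noise``
    Outcome:     ``theta·std(edu) + lambda_·S_midparent + conf_out·C + pop shift + noise``
    Binary:      indicator that an independently-noised copy of the outcome
                 liability exceeds its empirical ``1 − prev_binary`` quantile,
                 so the sample prevalence matches ``prev_binary`` by design.

    Noise variances are sized as ``1 − (sum of squared loadings)`` (floored at
    0.05) so each phenotype has near-unit variance and squared loadings read
    as variance shares; with all bias channels off the polygenic score's
    expected r² on education is exactly ``delta²``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = genotypes.shape[0]
    score_child = genotypes @ pairs.weights
    s_child = _standardize(score_child)
    mid = (pairs.father_score + pairs.mother_score) / 2.0
    s_mid_fam = _standardize(mid)
    s_mid = s_mid_fam[fam_idx]

    conf_fam = rng.standard_normal(pairs.n_families)
    conf = conf_fam[fam_idx]
    is_pop2 = (pairs.subpop[fam_idx] == 2).astype(float)

    edu_noise = np.sqrt(max(1.0 - params.delta**2 - params.eta**2
                            - params.conf_edu**2, 0.05))
    edu = (params.delta * s_child + params.eta * s_mid
           + params.conf_edu * conf + params.pop_shift_edu * is_pop2
           + edu_noise * rng.standard_normal(n))
    edu_std = _standardize(edu)

    out_noise = np.sqrt(max(1.0 - params.theta**2 - params.lambda_**2
                            - params.conf_out**2, 0.05))
    structural = (params.theta * edu_std + params.lambda_ * s_mid
                  + params.conf_out * conf + params.pop_shift_out * is_pop2)
    outcome = structural + out_noise * rng.standard_normal(n)
    liability = structural + out_noise * rng.standard_normal(n)
    cut = np.quantile(liability, 1.0 - params.prev_binary)
    binary = (liability > cut).astype(np.int8)

    info = variant_info(params.n_snps)
    df = pd.DataFrame(genotypes, columns=info["column"].to_list())
    df.insert(0, "individual_id", [f"i{k:07d}" for k in range(n)])
    df.insert(1, "family_id", [f"f{k:06d}" for k in fam_idx])
    df.insert(2, "sex", rng.binomial(1, 0.55, size=n).astype(np.int8))
    df.insert(3, "age", np.round(rng.uniform(40, 70, size=n), 1))
    df.insert(4, "subpop", pairs.subpop[fam_idx])
    df["edu_years"] = 13.0 + 3.0 * edu
    df["outcome"] = outcome
    df["outcome_bin"] = binary
    df["_confounder"] = conf
    df["_score_child"] = score_child
    df["_score_midparent"] = mid[fam_idx]
    return df


def simulate_cohort(params: SimParams) -> pd.DataFrame:
    """End-to-end simulation: parents → mating → transmission → phenotypes.

    Deterministic in ``params`` (including ``params.seed``); sub-stages draw
    from child streams of one seed sequence so the stages stay independent.
    """
    rng_mate, rng_kids, rng_phen = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence([params.seed, 1]).spawn(3)
    )
    # the pool stream replays weight/frequency draws identically to true_weight_table
    pool = simulate_parent_pool(
        params, np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    )
    pairs = pair_mates(pool, params.rho_am, rng_mate)
    sizes = _sibship_sizes(params, pairs.n_families, rng_kids)
    genotypes, fam_idx = transmit_genotypes(pairs, sizes, rng_kids)
    return generate_phenotypes(genotypes, fam_idx, pairs, params, rng_phen)


def inject_missingness(cohort: pd.DataFrame, rate: float,
                       seed: int | None = None,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Set eligible cells missing independently with probability ``rate``
    (missing completely at random).  Identifier columns are never eligible.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    if columns is None:
        protected = {"individual_id", "family_id", "subpop", *TRUTH_COLUMNS}
        columns = [c for c in out.columns if c not in protected]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(columns))) < rate
    block = out[columns].astype(float)
    block = block.mask(pd.DataFrame(mask, index=out.index, columns=columns))
    out[columns] = block
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 params: SimParams | None = None) -> None:
    """Write a cohort as TSV ("NA" for missing) with a JSON parameter sidecar."""
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(params), indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
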