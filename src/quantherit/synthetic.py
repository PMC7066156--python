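"""Gaussian-copula pedigree simulator.

Two-generation families (father, mother, k offspring) are drawn from a
multivariate normal latent scale with a constant familial correlation
structure — corr(father, mother) = rho_spouse, corr(parent, child) = rho_po,
corr(child, child) = rho_ss — and each latent value is pushed through the
standard normal CDF and the inverse CDF of a configurable margin (normal,
lognormal, or gamma).  Additive sex and age effects and repeated noisy exams
are layered on top, emitting the same pedigree/exam table dialect the reader
consumes.

Quantile-dependent familial effects arise purely from the margin: with a
skewed (e.g. lognormal) margin the raw-scale conditional quantile slopes rise
with the quantile level even though the latent correlation is constant, while
normal margins give a flat slope process.  This makes the generator a
controllable test bed for the pipeline's trend tests: ``null_config`` is the
flat case, ``signature_config`` the rising case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "oracle_quantile_slope",
    "null_config",
    "signature_config",
]

# sibship-size mix loosely matching a two-generation cohort study
# (singletons common; among multi-child sibships sizes 2..5 taper off)
DEFAULT_OFFSPRING_DIST = {1: 0.35, 2: 0.34, 3: 0.19, 4: 0.08, 5: 0.04}

EXAM_SPACING_YEARS = 4.0
PARENT_AGE_OFFSET = 25.0
VALUE_FLOOR = 1e-3  # concentrations are positive; guards the log transform


@dataclass(frozen=True)
class SyntheticConfig:
    n_families: int = 1000
    offspring_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSPRING_DIST)
    )
    rho_spouse: float = 0.15
    rho_po: float = 0.35
    rho_ss: float = 0.40
    margin: tuple = ("lognormal", 0.6, 0.6)  # (name, *params)
    sex_effect: float = -0.2
    age_effect: float = 0.02
    age2_effect: float = 0.0
    n_exams: int = 3
    exam_noise_sd: float = 0.3
    age_range: tuple[float, float] = (25.0, 55.0)
    seed: int = 0

    def margin_dist(self):
        name, *params = self.margin
        if name == "normal":
            return stats.norm(loc=params[0], scale=params[1])
        if name == "lognormal":
            return stats.lognorm(s=params[1], scale=np.exp(params[0]))
        if name == "gamma":
            return stats.gamma(a=params[0], scale=params[1])
        raise ValueError(f"unknown margin {name!r}")

    def correlation_matrix(self, k: int) -> np.ndarray:
        m = 2 + k
        R = np.full((m, m), self.rho_ss)
        R[:2, :] = self.rho_po
        R[:, :2] = self.rho_po
        R[0, 1] = R[1, 0] = self.rho_spouse
        np.fill_diagonal(R, 1.0)
        return R

    def validate(self) -> None:
        probs = np.array(list(self.offspring_dist.values()), float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("offspring_dist probabilities must be >= 0 and sum to 1")
        k_max = max(self.offspring_dist)
        eig = np.linalg.eigvalsh(self.correlation_matrix(k_max))
        if eig.min() <= 1e-10:
            raise ValueError(
                f"familial correlation matrix not positive definite for "
                f"sibship size {k_max} (min eigenvalue {eig.min():.3g})"
            )
        if self.n_exams < 1 or self.n_families < 1:
            raise ValueError("n_exams and n_families must be positive")


def _measurement(config, base, female, age, noise):
    raw = (
        base
        + config.sex_effect * female
        + config.age_effect * age
        + config.age2_effect * age**2
        + noise
    )
    return np.maximum(raw, VALUE_FLOOR)


def generate_cohort(config: SyntheticConfig, out_dir=None):
    """Draw a full two-generation cohort; returns (pedigree, exams) DataFrames.

    With ``out_dir`` set, also writes ``pedigree.tsv`` and ``exams.tsv``.
    Fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    margin = config.margin_dist()

    sizes = np.array(sorted(config.offspring_dist))
    probs = np.array([config.offspring_dist[k] for k in sizes])
    ks = rng.choice(sizes, size=config.n_families, p=probs)

    chol = {k: np.linalg.cholesky(config.correlation_matrix(k)) for k in sizes}

    ped_rows, exam_rows = [], []
    lo, hi = config.age_range
    for fam in range(config.n_families):
        k = int(ks[fam])
        z = chol[k] @ rng.standard_normal(2 + k)
        base = margin.ppf(stats.norm.cdf(z))

        fid, mid = f"F{fam:05d}", f"M{fam:05d}"
        members = [(fid, "M", "offspring", "", "")]
        members.append((mid, "F", "offspring", "", ""))
        for j in range(k):
            sex = "F" if rng.random() < 0.5 else "M"
            members.append((f"C{fam:05d}_{j}", sex, "gen3", fid, mid))

        ages0 = rng.uniform(lo, hi, size=2 + k)
        ages0[:2] += PARENT_AGE_OFFSET
        for i, (iid, sex, cohort, fa, mo) in enumerate(members):
            ped_rows.append((iid, fa, mo, sex, cohort))
            female = 1.0 if sex == "F" else 0.0
            noise = rng.normal(0.0, config.exam_noise_sd, size=config.n_exams)
            for e in range(config.n_exams):
                age = ages0[i] + EXAM_SPACING_YEARS * e
                val = _measurement(config, base[i], female, age, noise[e])
                exam_rows.append((iid, e + 1, round(age, 3), round(float(val), 6), 0))

    pedigree = pd.DataFrame(
        ped_rows, columns=["individual_id", "father_id", "mother_id", "sex", "cohort"]
    )
    exams = pd.DataFrame(
        exam_rows, columns=["individual_id", "exam_index", "age", "value", "on_lipid_meds"]
    )
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pedigree.to_csv(out_dir / "pedigree.tsv", sep="\t", index=False)
        exams.to_csv(out_dir / "exams.tsv", sep="\t", index=False)
    return pedigree, exams


_PAIR_RHO = {
    "OP": lambda c: c.rho_po,
    "FS": lambda c: c.rho_ss,
    "SPOUSE": lambda c: c.rho_spouse,
}


def oracle_quantile_slope(
    config: SyntheticConfig,
    tau: float,
    pair_kind: str = "OP",
    n_mc: int = 10**5,
    seed: int | None = None,
    include_exam_noise: bool = True,
) -> float:
    """Brute-force population quantile-regression slope for one pair kind.

    Simulates pairs directly from the latent model (no pedigree assembly, no
    covariates) and minimises the sample mean check loss over (intercept,
    slope) with a derivative-free optimiser — an oracle that shares no code
    with the production LP solver.  Exam-averaged measurement noise is
    included by default so the target matches what the pipeline estimates.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    margin = config.margin_dist()

    if pair_kind in _PAIR_RHO:
        rho = _PAIR_RHO[pair_kind](config)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_mc)
        vals = margin.ppf(stats.norm.cdf(z))
        y, x = vals[:, 0], vals[:, 1]
    elif pair_kind == "MIDPARENT":
        R = config.correlation_matrix(1)  # (father, mother, child)
        z = rng.multivariate_normal(np.zeros(3), R, size=n_mc)
        vals = margin.ppf(stats.norm.cdf(z))
        y = vals[:, 2]
        x = 0.5 * (vals[:, 0] + vals[:, 1])
    else:
        raise ValueError(f"unknown pair_kind {pair_kind!r}")

    if include_exam_noise:
        sd = config.exam_noise_sd / np.sqrt(config.n_exams)
        y = y + rng.normal(0.0, sd, size=n_mc)
        x = x + rng.normal(0.0, sd, size=n_mc)

    def loss(ab):
        u = y - ab[0] - ab[1] * x
        return float(np.mean(u * (tau - (u < 0))))

    b0 = np.cov(x, y)[0, 1] / np.var(x)
    a0 = np.quantile(y - b0 * x, tau)
    res = optimize.minimize(loss, x0=[a0, b0], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[1])


def null_config(seed: int = 0, n_families: int = 1000) -> SyntheticConfig:
    """Normal margins: constant-slope (flat heritability) reference case."""
    return SyntheticConfig(
        n_families=n_families, margin=("normal", 2.4, 1.0), seed=seed
    )


def signature_config(seed: int = 0, n_families: int = 1000) -> SyntheticConfig:
    """Lognormal margins: raw-scale slopes rise with the quantile level while
    the latent (log-scale) dependence stays constant."""
    return SyntheticConfig(
        n_families=n_families, margin=("lognormal", 0.6, 0.6), seed=seed
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
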