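"""Simulation studies that validate the estimator algebra.

Each function here runs a small, fully seeded simulation study and returns
the quantity of interest: the weight with which a parental or sibling
effect enters the stratified PGS association, the calibration of the
difference estimator, or the inflation induced by assortative mating.

Where a weight is recovered by sweeping one effect parameter, the same
family PGS draw and the same error vector are reused across the sweep
(common random numbers): the fitted slope is then exactly linear in the
swept parameter with the realized within-sample regression coefficient as
its weight, so the Monte-Carlo noise of the recovered weight is that of a
single realized correlation rather than of a difference of independent
slopes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .family_sim import (
    EffectParams,
    FamilyPGSSet,
    MatingStructure,
    custom_structure,
    model1_structure,
    model2_structure,
    ols_slope,
    sample_family_pgs,
    simulate_phenotypes,
)

__all__ = [
    "singleton_maternal_weight",
    "nonsingleton_sibling_weight",
    "sibship_size_weight",
    "maternal_bias_weight",
    "model2_parent_offspring_corr",
    "difference_calibration",
    "model2_inflation",
]


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _sweep_weight(
    pgs: FamilyPGSSet,
    base: EffectParams,
    param: str,
    values: tuple[float, ...],
    eps_seed: int,
) -> float:
    """Slope of fitted OLS slope on the swept effect parameter."""
    slopes = []
    for v in values:
        y = simulate_phenotypes(pgs, replace(base, **{param: v}), seed=eps_seed)
        slopes.append(ols_slope(pgs.member("O1"), y.y)[0])
    x = np.asarray(values)
    s = np.asarray(slopes)
    return float(np.polyfit(x, s, 1)[0])


def singleton_maternal_weight(
    n: int = 100_000,
    values: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    seed: int = 0,
) -> float:
    """Weight of the maternal IGE in the singleton association (expected 0.5).

    Sweeps k_M in Model-1 trios with k_I = 0.5, k_P = 0.1, C = 0 fixed.
    """
    s1, s2 = _spawn(seed, 2)
    pgs = sample_family_pgs(n, model1_structure(1), "trio", seed=s1)
    base = EffectParams(k_I=0.5, k_P=0.1)
    return _sweep_weight(pgs, base, "k_M", values, s2)


def nonsingleton_sibling_weight(
    n: int = 100_000,
    values: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    seed: int = 0,
) -> float:
    """Weight of one sibling's IGE in the non-singleton association (expected 0.5).

    Sweeps k_S in Model-1 quads with k_I = 0.5, k_M = k_P = 0.1, C = 0 fixed.
    """
    s1, s2 = _spawn(seed, 2)
    pgs = sample_family_pgs(n, model1_structure(2), "quad", seed=s1)
    base = EffectParams(k_I=0.5, k_M=0.1, k_P=0.1)
    return _sweep_weight(pgs, base, "k_S", values, s2)


def sibship_size_weight(
    n: int = 100_000,
    sizes: tuple[int, ...] = (1, 2, 3, 4),
    k_S: float = 0.2,
    seed: int = 0,
) -> float:
    """Per-additional-sibling slope increment divided by k_S (expected 0.5).

    For each number of siblings N the index individual's phenotype sums the
    IGEs of all N siblings; the fitted slope is regressed on N.
    """
    seeds = _spawn(seed, 2 * len(sizes))
    base = EffectParams(k_I=0.5, k_M=0.1, k_P=0.1, k_S=k_S)
    slopes = []
    for i, n_sibs in enumerate(sizes):
        structure = model1_structure(n_sibs + 1)
        pgs = sample_family_pgs(
            n, structure, f"sibship({n_sibs + 1})", seed=seeds[2 * i]
        )
        y = simulate_phenotypes(pgs, base, seed=seeds[2 * i + 1])
        slopes.append(ols_slope(pgs.member("O1"), y.y)[0])
    increment = float(np.polyfit(np.asarray(sizes, float), np.asarray(slopes), 1)[0])
    return increment / k_S


def maternal_bias_weight(
    n: int = 100_000,
    k_m_singleton: float = 0.1,
    k_m_nonsingleton: float = 0.3,
    seed: int = 0,
) -> float:
    """Bias weight of maternal-IGE heterogeneity on the unscaled difference.

    The singleton and non-singleton strata differ only in k_M (sibling
    effect zero), so (beta_NS - beta_S) / (k_NS,M - k_S,M) recovers the 0.5
    weight of the bias formula.  The trio stratum reuses the M, P, O1
    columns of the quad draw and the same error vector, so everything but
    the maternal-effect difference cancels exactly.
    """
    s1, s2 = _spawn(seed, 2)
    quads = sample_family_pgs(n, model1_structure(2), "quad", seed=s1)
    # Model-1 (M,P,O1) marginal of the quad structure == the trio structure
    trios = FamilyPGSSet(
        structure=model1_structure(1), pgs=quads.pgs[:, :3], kind="trio"
    )
    common = dict(k_I=0.5, k_P=0.1)
    y_ns = simulate_phenotypes(
        quads, EffectParams(k_M=k_m_nonsingleton, k_S=0.0, **common), seed=s2
    )
    y_s = simulate_phenotypes(
        trios, EffectParams(k_M=k_m_singleton, **common), seed=s2
    )
    beta_ns = ols_slope(quads.member("O1"), y_ns.y)[0]
    beta_s = ols_slope(trios.member("O1"), y_s.y)[0]
    return (beta_ns - beta_s) / (k_m_nonsingleton - k_m_singleton)


def model2_parent_offspring_corr(n: int = 100_000, seed: int = 0) -> float:
    """Realized maternal–offspring PGS correlation under assortative mating."""
    pgs = sample_family_pgs(n, model2_structure(2), "quad", seed=seed)
    return float(np.corrcoef(pgs.member("M"), pgs.member("O1"))[0, 1])


def _one_difference(
    n: int,
    effects: EffectParams,
    structure_trio: MatingStructure,
    structure_quad: MatingStructure,
    seeds: list[int],
) -> tuple[float, float]:
    """One replicate: 2*(beta_NS - beta_S) and its delta-method SE."""
    trio = sample_family_pgs(n, structure_trio, "trio", seed=seeds[0])
    quad = sample_family_pgs(n, structure_quad, "quad", seed=seeds[1])
    y_s = simulate_phenotypes(trio, replace(effects, k_S=0.0), seed=seeds[2])
    y_ns = simulate_phenotypes(quad, effects, seed=seeds[3])
    b_s, se_s = ols_slope(trio.member("O1"), y_s.y)
    b_ns, se_ns = ols_slope(quad.member("O1"), y_ns.y)
    return 2.0 * (b_ns - b_s), 2.0 * float(np.hypot(se_s, se_ns))


def difference_calibration(
    n_replicates: int = 200,
    n: int = 20_000,
    effects: EffectParams | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Bias and CI coverage of the scaled difference estimator (Model 1).

    Returns the replicate mean and SE of 2*(beta_NS - beta_S), the true
    k_S, and the fraction of 95% CIs covering k_S.
    """
    effects = effects or EffectParams(k_I=0.5, k_M=0.1, k_P=0.1, k_S=0.2)
    trio_s, quad_s = model1_structure(1), model1_structure(2)
    seeds = _spawn(seed, 4 * n_replicates)
    ests, covered = [], 0
    for r in range(n_replicates):
        est, se = _one_difference(
            n, effects, trio_s, quad_s, seeds[4 * r : 4 * r + 4]
        )
        ests.append(est)
        if abs(est - effects.k_S) <= 1.959963984540054 * se:
            covered += 1
    ests = np.asarray(ests)
    return {
        "mean": float(ests.mean()),
        "se_of_mean": float(ests.std(ddof=1) / np.sqrt(n_replicates)),
        "k_S": effects.k_S,
        "coverage": covered / n_replicates,
    }


def model2_inflation(
    n_replicates: int = 200,
    n: int = 50_000,
    effects: EffectParams | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of assortative-mating replicates with 2*(beta_NS-beta_S) > k_S."""
    effects = effects or EffectParams(k_I=0.5, k_M=0.1, k_P=0.1, k_S=0.2)
    trio_s, quad_s = model2_structure(1), model2_structure(2)
    seeds = _spawn(seed, 4 * n_replicates)
    ests = [
        _one_difference(n, effects, trio_s, quad_s, seeds[4 * r : 4 * r + 4])[0]
        for r in range(n_replicates)
    ]
    ests = np.asarray(ests)
    return {
        "mean": float(ests.mean()),
        "k_S": effects.k_S,
        "frac_above_k_S": float((ests > effects.k_S).mean()),
    }
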