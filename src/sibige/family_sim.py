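"""Family-structured polygenic-score simulation and analytic expectations.

Families are simulated at the score level: each member (mother M, father P,
offspring O1..On) carries a standardized polygenic score (PGS), and the set
of within-family PGS correlations — spousal, parent–offspring, sibling —
defines the mating regime.  Under random mating the spousal correlation is 0
and parent–offspring and sibling correlations are 0.5; assortative mating
raises them (here to 0.2 and 0.6, the non-random-mating scenario).

The index individual is always offspring O1.  Their phenotype is a linear
combination of family PGS:

    y = (k_I + C) * G_O1 + k_M * G_M + k_P * G_P + k_S * sum(G_sibs) + eps

where k_I is the direct effect, k_M / k_P parental indirect genetic effects
(IGEs), k_S the per-sibling IGE, C a confounding slope shift on the index
individual's own score, and eps ~ N(0, sigma_eps^2).

The population OLS slope of y on G_O1 then has the closed form

    beta = k_I + 0.5*k_M + 0.5*k_P + n_sibs * 0.5 * k_S + C

under random mating, which :func:`expected_slope` returns and against which
all estimators in this package are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MatingStructure",
    "EffectParams",
    "FamilyPGSSet",
    "PhenotypeVector",
    "model1_structure",
    "model2_structure",
    "sample_family_pgs",
    "simulate_phenotypes",
    "expected_slope",
    "expected_bias",
]

#: Canonical correlation values under random mating.
MODEL1 = {"spousal": 0.0, "parent_offspring": 0.5, "sibling": 0.5}
#: Canonical correlation values under assortative mating.
MODEL2 = {"spousal": 0.2, "parent_offspring": 0.6, "sibling": 0.6}

_PSD_TOL = 1e-10


def _member_labels(n_offspring: int) -> list[str]:
    return ["M", "P"] + [f"O{i + 1}" for i in range(n_offspring)]


@dataclass(frozen=True)
class MatingStructure:
    """Within-family PGS correlation matrix over (M, P, O1..On).

    Parameters
    ----------
    member_labels
        Ordered member names, always ``["M", "P", "O1", ..., "On"]``.
    corr
        Symmetric positive-semidefinite correlation matrix with unit
        diagonal; sibling–sibling and parent–offspring entries must each be
        constant across pairs.
    """

    member_labels: tuple[str, ...]
    corr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        k = len(self.member_labels)
        if corr.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {corr.shape} does not match "
                f"{k} member labels"
            )
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have a unit diagonal")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -_PSD_TOL:
            raise ValueError(
                "correlation matrix is not positive semidefinite: "
                f"smallest eigenvalue {eigmin:.6g} < 0"
            )
        # parent-offspring and sibling entries must be constant across pairs
        off = [i for i, lab in enumerate(self.member_labels) if lab.startswith("O")]
        po = {corr[p, o] for p in (0, 1) for o in off}
        if len({round(v, 12) for v in po}) > 1:
            raise ValueError("parent–offspring correlations differ across pairs")
        ss = {corr[a, b] for a in off for b in off if a < b}
        if len({round(v, 12) for v in ss}) > 1:
            raise ValueError("sibling–sibling correlations differ across pairs")

    @property
    def n_members(self) -> int:
        return len(self.member_labels)

    @property
    def n_offspring(self) -> int:
        return self.n_members - 2


def _build_structure(
    n_offspring: int, spousal: float, parent_offspring: float, sibling: float
) -> MatingStructure:
    labels = _member_labels(n_offspring)
    k = len(labels)
    corr = np.eye(k)
    corr[0, 1] = corr[1, 0] = spousal
    for o in range(2, k):
        corr[0, o] = corr[o, 0] = parent_offspring
        corr[1, o] = corr[o, 1] = parent_offspring
        for o2 in range(o + 1, k):
            corr[o, o2] = corr[o2, o] = sibling
    return MatingStructure(tuple(labels), corr)


def model1_structure(n_offspring: int = 1) -> MatingStructure:
    """Random-mating structure: spousal 0, parent–offspring/sibling 0.5."""
    return _build_structure(n_offspring, **MODEL1)


def model2_structure(n_offspring: int = 1) -> MatingStructure:
    """Assortative-mating structure: spousal 0.2, others 0.6."""
    return _build_structure(n_offspring, **MODEL2)


def custom_structure(
    n_offspring: int, spousal: float, parent_offspring: float, sibling: float
) -> MatingStructure:
    """Structure with user-chosen spousal/parent–offspring/sibling correlations."""
    return _build_structure(n_offspring, spousal, parent_offspring, sibling)


@dataclass(frozen=True)
class EffectParams:
    """Phenotype-model effects, in trait units per SD of PGS.

    ``k_I`` is the direct effect of the index individual's own score; ``k_M``
    and ``k_P`` are maternal and paternal IGEs; ``k_S`` is the IGE of one
    sibling (summing over siblings in larger sibships); ``C`` is a
    confounding shift added to the slope on the index individual's own score;
    ``sigma_eps`` scales the independent Gaussian error.  ``stratum``
    optionally labels a stratum-specific parameter set.
    """

    k_I: float = 0.0
    k_M: float = 0.0
    k_P: float = 0.0
    k_S: float = 0.0
    C: float = 0.0
    sigma_eps: float = 1.0
    stratum: str | None = None

    def __post_init__(self) -> None:
        vals = (self.k_I, self.k_M, self.k_P, self.k_S, self.C, self.sigma_eps)
        if not all(np.isfinite(vals)):
            raise ValueError("all effect parameters must be finite")
        if self.sigma_eps <= 0:
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")

    def with_stratum(self, label: str) -> "EffectParams":
        return replace(self, stratum=label)


@dataclass(frozen=True)
class FamilyPGSSet:
    """Standardized PGS draws for ``n_families`` families.

    ``pgs`` has one row per family and one column per member, ordered as in
    ``structure.member_labels``.  ``kind`` is "trio", "quad" or "sibship".
    """

    structure: MatingStructure
    pgs: np.ndarray = field(repr=False)
    kind: str = "trio"

    @property
    def n_families(self) -> int:
        return self.pgs.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.structure.n_offspring

    def member(self, label: str) -> np.ndarray:
        return self.pgs[:, self.structure.member_labels.index(label)]

    def realized_corr(self) -> np.ndarray:
        return np.corrcoef(self.pgs, rowvar=False)


@dataclass(frozen=True)
class PhenotypeVector:
    """Index-individual phenotypes with the generating parameters attached."""

    y: np.ndarray = field(repr=False)
    generator_params: EffectParams = field(default_factory=EffectParams)


def _kind_offspring(kind: str) -> int:
    if kind == "trio":
        return 1
    if kind == "quad":
        return 2
    if kind.startswith("sibship"):
        n = int(kind.split("(")[1].rstrip(")")) if "(" in kind else 1
        if n < 1:
            raise ValueError("sibship kind needs at least one offspring")
        return n
    raise ValueError(f"unknown family kind {kind!r}")


def sample_family_pgs(
    n_families: int,
    structure: MatingStructure,
    kind: str = "trio",
    seed: int | np.random.Generator = 0,
) -> FamilyPGSSet:
    """Draw families of standardized PGS from the mating structure.

    Exact multivariate-normal sampling via the Cholesky factor of the
    correlation matrix; deterministic given ``seed`` (an int or a numpy
    Generator).

    ``kind`` is ``"trio"`` (one offspring), ``"quad"`` (sibling pair) or
    ``"sibship(n)"``; it must match ``structure``'s member count.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    n_off = _kind_offspring(kind)
    if structure.n_offspring != n_off:
        raise ValueError(
            f"kind {kind!r} implies {n_off} offspring but structure has "
            f"{structure.n_offspring}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(structure.corr)
    except np.linalg.LinAlgError:
        # PSD-but-singular matrices: eigendecomposition factor
        w, v = np.linalg.eigh(structure.corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_families, structure.n_members))
    return FamilyPGSSet(structure=structure, pgs=z @ chol.T, kind=kind)


def simulate_phenotypes(
    pgs: FamilyPGSSet,
    effects: EffectParams,
    seed: int | np.random.Generator = 0,
) -> PhenotypeVector:
    """Simulate the index individual's (O1's) phenotype.

    y = (k_I + C) * G_O1 + k_M * G_M + k_P * G_P + k_S * sum(G_sibs) + eps,
    eps ~ N(0, sigma_eps^2).  ``k_S`` may be nonzero only when the family
    has at least one sibling of the index individual.
    """
    if effects.k_S != 0.0 and pgs.n_offspring < 2:
        raise ValueError(
            "k_S is nonzero but families have no sibling of the index individual"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = (
        (effects.k_I + effects.C) * pgs.member("O1")
        + effects.k_M * pgs.member("M")
        + effects.k_P * pgs.member("P")
    )
    for i in range(2, pgs.n_offspring + 1):
        y = y + effects.k_S * pgs.member(f"O{i}")
    y = y + rng.normal(0.0, effects.sigma_eps, size=pgs.n_families)
    return PhenotypeVector(y=y, generator_params=effects)


def expected_slope(
    effects: EffectParams, stratum: str = "non-singleton", n_sibs: int = 1
) -> float:
    """Closed-form population OLS slope of phenotype on own PGS.

    Under random mating: k_I + 0.5*k_M + 0.5*k_P + n_sibs*0.5*k_S + C.
    Singletons have ``n_sibs = 0`` and receive no sibling term.
    """
    if n_sibs < 0:
        raise ValueError("n_sibs must be non-negative")
    if (stratum == "singleton") != (n_sibs == 0):
        raise ValueError("n_sibs must be 0 exactly for the singleton stratum")
    return (
        effects.k_I
        + 0.5 * effects.k_M
        + 0.5 * effects.k_P
        + n_sibs * 0.5 * effects.k_S
        + effects.C
    )


def expected_bias(
    effects_ns: EffectParams, effects_s: EffectParams
) -> dict[str, float]:
    """Additive decomposition of the expected unscaled difference beta_NS - beta_S.

    For one-sibling non-singletons the difference decomposes as

        0.5*k_S  +  (k_NS,I - k_S,I)  +  0.5*(k_NS,M - k_S,M)
                 +  0.5*(k_NS,P - k_S,P)  +  (C_NS - C_S)

    returned as ``sibling_term``, ``direct_term``, ``maternal_term``,
    ``paternal_term`` and ``confounder_term``.  The components sum exactly to
    ``expected_slope(ns, n_sibs=1) - expected_slope(s, "singleton", 0)``.
    """
    return {
        "sibling_term": 0.5 * effects_ns.k_S,
        "direct_term": effects_ns.k_I - effects_s.k_I,
        "maternal_term": 0.5 * (effects_ns.k_M - effects_s.k_M),
        "paternal_term": 0.5 * (effects_ns.k_P - effects_s.k_P),
        "confounder_term": effects_ns.C - effects_s.C,
    }


def ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope of y on x and its classical SE."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    return beta, float(np.sqrt(sigma2 / sxx))


def summarize_families(
    pgs: FamilyPGSSet, y: PhenotypeVector | None = None
) -> "pd.DataFrame":
    """Summary table: realized correlations vs targets, and the fitted slope."""
    import pandas as pd

    labels = pgs.structure.member_labels
    realized = pgs.realized_corr()
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "quantity": f"corr({labels[i]},{labels[j]})",
                    "target": pgs.structure.corr[i, j],
                    "realized": realized[i, j],
                }
            )
    for lab in labels:
        rows.append(
            {"quantity": f"var({lab})", "target": 1.0, "realized": pgs.member(lab).var()}
        )
    if y is not None:
        beta, se = ols_slope(pgs.member("O1"), y.y)
        p = y.generator_params
        rows.append(
            {
                "quantity": "slope(y~O1)",
                "target": expected_slope(
                    p,
                    "singleton" if pgs.n_offspring == 1 else "non-singleton",
                    pgs.n_offspring - 1,
                ),
                "realized": beta,
            }
        )
        rows.append({"quantity": "slope_se", "target": np.nan, "realized": se})
    return pd.DataFrame(rows)
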