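"""Synthetic biobank-style cohort generator.

Emulates the statistical structure of a large population cohort of
unrelated, genotyped adults: per-individual standardized PGS for several
traits, phenotypes generated under the family IGE model, sex, birth year,
ten genetic principal components, self-reported counts of full brothers /
full sisters / older siblings (with partial item missingness), and an
adoption flag.

For each individual a full sibship of size N (drawn from a categorical
distribution) plus two parents is simulated via
:mod:`sibige.family_sim`; the index individual's phenotype receives the
k_S contribution of every sibling's PGS (or of older siblings only, when
``older_sib_only_ige`` is set) and then all relatives' scores are
discarded, mirroring a sample of unrelateds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .family_sim import (
    EffectParams,
    MatingStructure,
    custom_structure,
    model1_structure,
    model2_structure,
)

__all__ = ["TraitConfig", "CohortConfig", "simulate_cohort", "assign_strata"]

# Truncated categorical over number of full siblings, matched to the study
# cohort's gross margins: ~13% singletons and ~4.9% reporting 6+ siblings.
DEFAULT_SIBSHIP_DIST: dict[int, float] = {
    0: 0.130,
    1: 0.340,
    2: 0.250,
    3: 0.140,
    4: 0.060,
    5: 0.031,
    6: 0.025,
    7: 0.012,
    8: 0.007,
    9: 0.005,
}

MISSING_SENTINEL = "NA"


@dataclass(frozen=True)
class TraitConfig:
    """One simulated trait: its effect parameters and generator options.

    ``effects`` applies everywhere unless ``effects_by_size`` overrides the
    parameter set for specific sibship sizes (number of siblings of the
    index individual) — used e.g. to attenuate effects in very large
    families.
    """

    name: str
    effects: EffectParams = field(default_factory=EffectParams)
    effects_by_size: dict[int, EffectParams] = field(default_factory=dict)
    phenotype_sd: float = 1.0

    def effects_for(self, n_sibs: int) -> EffectParams:
        return self.effects_by_size.get(n_sibs, self.effects)


@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 10_000
    traits: tuple[TraitConfig, ...] = (TraitConfig("trait"),)
    sibship_size_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIBSHIP_DIST)
    )
    older_sib_only_ige: bool = False
    adoption_rate: float = 0.016
    sibling_question_missingness: float = 0.01
    male_proportion: float = 0.46
    birth_year_range: tuple[int, int] = (1936, 1970)
    n_pcs: int = 10
    pc_confounding: float = 0.0  # PC1 -> PGS and PC1 -> phenotype path strength
    mating: str = "model1"  # model1 | model2
    seed: int = 0

    def __post_init__(self) -> None:
        dist = self.sibship_size_distribution
        if not dist:
            raise ValueError("sibship size distribution must be non-empty")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"sibship size distribution sums to {total}, not 1")
        if any(p < 0 for p in dist.values()) or any(k < 0 for k in dist):
            raise ValueError("sibship sizes and probabilities must be non-negative")
        for p, name in [
            (self.adoption_rate, "adoption_rate"),
            (self.sibling_question_missingness, "sibling_question_missingness"),
            (self.male_proportion, "male_proportion"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def structure_for(self, n_sibs: int) -> MatingStructure:
        n_off = n_sibs + 1
        if self.mating == "model1":
            return model1_structure(n_off)
        if self.mating == "model2":
            return model2_structure(n_off)
        raise ValueError(f"unknown mating preset {self.mating!r}")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        if "traits" in raw:
            traits = []
            for t in raw["traits"]:
                t = dict(t)
                eff = EffectParams(**t.pop("effects", {}))
                by_size = {
                    int(k): EffectParams(**v)
                    for k, v in t.pop("effects_by_size", {}).items()
                }
                traits.append(
                    TraitConfig(effects=eff, effects_by_size=by_size, **t)
                )
            raw["traits"] = tuple(traits)
        if "sibship_size_distribution" in raw:
            raw["sibship_size_distribution"] = {
                int(k): float(v) for k, v in raw["sibship_size_distribution"].items()
            }
        if "birth_year_range" in raw:
            raw["birth_year_range"] = tuple(raw["birth_year_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the cohort table, one row per index individual.

    Columns: ``id``, ``pgs_<trait>``, ``<trait>`` (phenotype), ``sex``
    (1 = male), ``birth_year``, ``pc1..pc<k>``, ``n_brothers``,
    ``n_sisters``, ``n_older_sibs`` (floats, NaN = unanswered question),
    ``adopted``, plus the true generator-side ``true_n_siblings`` and
    ``birth_order`` (1-based position among the N+1 children).

    Individuals are generated in groups sharing a sibship size so the
    family draws vectorize; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    sizes = np.array(sorted(config.sibship_size_distribution), dtype=int)
    probs = np.array([config.sibship_size_distribution[s] for s in sizes])
    n_sibs = rng.choice(sizes, size=n, p=probs / probs.sum())

    sex = (rng.random(n) < config.male_proportion).astype(int)
    y0, y1 = config.birth_year_range
    birth_year = rng.integers(y0, y1 + 1, size=n)
    pcs = rng.standard_normal((n, config.n_pcs))
    adopted = rng.random(n) < config.adoption_rate

    # birth order uniform among the N+1 sibship positions
    birth_order = 1 + (rng.random(n) * (n_sibs + 1)).astype(int)

    pgs_cols = {t.name: np.empty(n) for t in config.traits}
    pheno_cols = {t.name: np.empty(n) for t in config.traits}

    for size in sizes:
        idx = np.nonzero(n_sibs == size)[0]
        if idx.size == 0:
            continue
        structure = config.structure_for(int(size))
        chol = np.linalg.cholesky(structure.corr)
        for trait in config.traits:
            eff = trait.effects_for(int(size))
            z = rng.standard_normal((idx.size, structure.n_members))
            fam = z @ chol.T  # columns: M, P, O1 (index), O2..O(size+1)
            g_m, g_p, g_i = fam[:, 0], fam[:, 1], fam[:, 2]
            if config.pc_confounding:
                g_i = g_i + config.pc_confounding * pcs[idx, 0]
            y = (eff.k_I + eff.C) * g_i + eff.k_M * g_m + eff.k_P * g_p
            if size > 0 and eff.k_S != 0.0:
                sib_pgs = fam[:, 3:]
                if config.older_sib_only_ige:
                    # siblings occupy the other positions; those with position
                    # < index birth order are older. Positions are exchange-
                    # able, so the first (birth_order-1) sibling columns act
                    # as the older siblings.
                    n_older = birth_order[idx] - 1
                    mask = np.arange(size)[None, :] < n_older[:, None]
                    y = y + eff.k_S * (sib_pgs * mask).sum(axis=1)
                else:
                    y = y + eff.k_S * sib_pgs.sum(axis=1)
            y = y + rng.normal(0.0, eff.sigma_eps, size=idx.size)
            if config.pc_confounding:
                y = y + config.pc_confounding * pcs[idx, 0]
            pgs_cols[trait.name][idx] = g_i
            pheno_cols[trait.name][idx] = trait.phenotype_sd * y

    # split true sibling count into reported brothers/sisters
    n_brothers = rng.binomial(n_sibs, 0.5).astype(float)
    n_sisters = (n_sibs - n_brothers).astype(float)
    n_older = (birth_order - 1).astype(float)

    # item missingness: each sibling question independently unanswered
    miss_b = rng.random(n) < config.sibling_question_missingness
    miss_s = rng.random(n) < config.sibling_question_missingness
    n_brothers[miss_b] = np.nan
    n_sisters[miss_s] = np.nan

    data = {"id": np.arange(1, n + 1)}
    for t in config.traits:
        data[f"pgs_{t.name}"] = pgs_cols[t.name]
    for t in config.traits:
        data[t.name] = pheno_cols[t.name]
    data.update(
        sex=sex,
        birth_year=birth_year,
        **{f"pc{i + 1}": pcs[:, i] for i in range(config.n_pcs)},
        n_brothers=n_brothers,
        n_sisters=n_sisters,
        n_older_sibs=n_older,
        adopted=adopted.astype(int),
        true_n_siblings=n_sibs,
        birth_order=birth_order,
    )
    return pd.DataFrame(data)


def assign_strata(cohort: pd.DataFrame, top_category: int = 6) -> pd.DataFrame:
    """Attach stratum labels from self-reported sibling counts.

    Adopted individuals are removed.  Singleton status follows the
    self-report rule: both questions answered zero -> singleton; any
    reported sibling -> non-singleton; one question zero and the other
    unanswered -> status missing.  Firstborns report no older siblings.
    Sibship-size categories are "0".."<top-1>" and "<top>+".
    """
    for col in ("n_brothers", "n_sisters"):
        if (cohort[col].dropna() < 0).any():
            raise ValueError(f"negative sibling counts in {col}")
    out = cohort.loc[cohort["adopted"] == 0].copy()

    nb, ns = out["n_brothers"], out["n_sisters"]
    singleton = pd.Series(pd.NA, index=out.index, dtype="boolean")
    singleton[(nb == 0) & (ns == 0)] = True
    singleton[(nb > 0) | (ns > 0)] = False
    out["singleton"] = singleton
    out["n_siblings"] = (nb + ns).where(~(nb.isna() | ns.isna()))

    out["firstborn"] = pd.array(out["n_older_sibs"] == 0, dtype="boolean")
    out.loc[out["n_older_sibs"].isna(), "firstborn"] = pd.NA

    def _cat(v: float) -> str | pd.api.typing.NAType:
        if pd.isna(v):
            return pd.NA
        return f"{top_category}+" if v >= top_category else str(int(v))

    out["sibship_category"] = out["n_siblings"].map(_cat)
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=MISSING_SENTINEL)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING_SENTINEL])
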