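"""End-to-end desk-scale replication pipeline.

Runs every analysis stage in order on a synthetic cohort: stratum
assignment, singleton/non-singleton PGS associations and differences per
trait, firstborn/non-firstborn analyses, per-sibship-size associations,
linear and quadratic sibling-number interaction models (with and without
the 6+-sibling exclusion), the x2 sibling-IGE scaling, and group-level
difference tables.  Every stage is a pure function of (config, seed); the
report and all intermediate tables are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_sim import CohortConfig, assign_strata, simulate_cohort, write_cohort
from .estimators import (
    DEFAULT_COVARIATES,
    associations_by_sibship,
    estimate_difference,
    estimates_table,
    fit_association,
    fit_sibling_interaction,
    scale_sibling_ige,
)

logger = logging.getLogger("sibige")

__all__ = ["ReplicationReport", "run_replication"]


@dataclass
class ReplicationReport:
    """Bundle of every stage's results plus run provenance."""

    associations: pd.DataFrame
    differences: pd.DataFrame
    by_sibship: pd.DataFrame
    interactions: pd.DataFrame
    ige: pd.DataFrame
    group_diffs: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "associations", "differences", "by_sibship", "interactions",
            "ige", "group_diffs",
        ):
            getattr(self, name).to_csv(
                out / f"{name}.tsv", sep="\t", index=False, na_rep="NA",
                float_format="%.10g",
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _config_hash(config: CohortConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def run_replication(
    config: CohortConfig,
    covariates: list[str] | None = None,
    out_dir=None,
    group_diff_variables: list[str] | None = None,
) -> ReplicationReport:
    """Run the full analysis chain on a freshly simulated cohort."""
    from .estimators import group_differences  # local to keep import cycle flat

    covariates = (
        list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    )
    stage = "simulate_cohort"
    try:
        cohort = simulate_cohort(config)
        logger.info("simulated %d individuals", len(cohort))
        stage = "assign_strata"
        labelled = assign_strata(cohort)
        logger.info(
            "after adoption exclusion: %d rows (%d removed); "
            "%d singletons, %d non-singletons, %d stratum-missing",
            len(labelled), len(cohort) - len(labelled),
            int((labelled["singleton"] == True).sum()),   # noqa: E712
            int((labelled["singleton"] == False).sum()),  # noqa: E712
            int(labelled["singleton"].isna().sum()),
        )
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            write_cohort(labelled, Path(out_dir) / "cohort.tsv")

        assoc, diffs, sib_rows, inter_rows, ige_rows = [], [], [], [], []
        for trait in config.traits:
            stage = f"fit_association[{trait.name}]"
            by_stratum = {}
            for stratum in ("singleton", "non-singleton", "firstborn", "non-firstborn"):
                est = fit_association(
                    labelled, trait.name, stratum=stratum, covariates=covariates
                )
                by_stratum[stratum] = est
                assoc.append(est)
            stage = f"estimate_difference[{trait.name}]"
            d_sing = estimate_difference(
                by_stratum["non-singleton"], by_stratum["singleton"],
                reference="a", label=f"{trait.name}: non-singleton - singleton",
            )
            d_first = estimate_difference(
                by_stratum["non-firstborn"], by_stratum["firstborn"],
                reference="a", label=f"{trait.name}: non-firstborn - firstborn",
            )
            d_fb_s = estimate_difference(
                by_stratum["firstborn"], by_stratum["singleton"],
                reference=None, label=f"{trait.name}: firstborn - singleton",
            )
            diffs += [d_sing, d_first, d_fb_s]

            stage = f"associations_by_sibship[{trait.name}]"
            per_cat, top_diff = associations_by_sibship(
                labelled, trait.name, covariates=covariates
            )
            sib_rows.append(estimates_table(per_cat, f"by_sibship:{trait.name}"))
            if top_diff is not None:
                sib_rows.append(
                    estimates_table([top_diff], f"by_sibship_diff:{trait.name}")
                )

            stage = f"fit_sibling_interaction[{trait.name}]"
            lin = fit_sibling_interaction(
                labelled, trait.name, "linear", "none", covariates=covariates
            )
            quad = fit_sibling_interaction(
                labelled, trait.name, "quadratic", "none", covariates=covariates
            )
            lin_x = fit_sibling_interaction(
                labelled, trait.name, "linear", "6+_removed", covariates=covariates
            )
            for label, est in (
                ("linear", lin), ("quadratic", quad), ("linear_6+_removed", lin_x),
            ):
                row = {
                    "trait": trait.name, "model": label, "n": est.n,
                    "beta_NxPGS": est.beta_NxPGS, "se_NxPGS": est.se_NxPGS,
                    "p_NxPGS": est.p_NxPGS,
                    "beta_N2xPGS": est.beta_N2xPGS, "se_N2xPGS": est.se_N2xPGS,
                }
                inter_rows.append(row)

            stage = f"scale_sibling_ige[{trait.name}]"
            ige = scale_sibling_ige(lin_x)
            ige_rows.append(
                {
                    "trait": trait.name, "source": "interaction_6+_removed",
                    "k_S_hat": ige.k_S_hat, "se": ige.se,
                    "ci_low": ige.ci95[0], "ci_high": ige.ci95[1],
                }
            )
            ige2 = scale_sibling_ige(d_sing)
            ige_rows.append(
                {
                    "trait": trait.name, "source": "singleton_difference",
                    "k_S_hat": ige2.k_S_hat, "se": ige2.se,
                    "ci_low": ige2.ci95[0], "ci_high": ige2.ci95[1],
                }
            )

        stage = "group_differences"
        if group_diff_variables is None:
            group_diff_variables = ["sex", "birth_year"] + [
                t.name for t in config.traits
            ]
        gd_unadj = group_differences(
            labelled, ["sex", "birth_year"], adjustment="none"
        )
        gd_adj = group_differences(
            labelled,
            [v for v in group_diff_variables if v not in ("sex", "birth_year")],
            adjustment="sex+age",
        )
        gd = pd.concat(
            [gd_unadj.assign(adjustment="none"), gd_adj.assign(adjustment="sex+age")],
            ignore_index=True,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    diff_rows = []
    for d in diffs:
        diff_rows.append(
            {
                "label": d.label, "delta": d.delta, "se": d.se_delta,
                "ci_low": d.ci95[0], "ci_high": d.ci95[1], "p": d.p,
                "attenuation_pct": d.attenuation_pct,
                "attenuation_ci_low": (
                    d.attenuation_ci95[0] if d.attenuation_ci95 else None
                ),
                "attenuation_ci_high": (
                    d.attenuation_ci95[1] if d.attenuation_ci95 else None
                ),
            }
        )

    report = ReplicationReport(
        associations=estimates_table(assoc, "stratified_association"),
        differences=pd.DataFrame(diff_rows),
        by_sibship=pd.concat(sib_rows, ignore_index=True)
        if sib_rows
        else pd.DataFrame(),
        interactions=pd.DataFrame(inter_rows),
        ige=pd.DataFrame(ige_rows),
        group_diffs=gd,
        manifest={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_individuals": config.n_individuals,
            "traits": [t.name for t in config.traits],
            "covariates": covariates,
            "version": __version__,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
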