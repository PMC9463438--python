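"""Decomposition of SES and polygenic-score effects on verbal ability.

Parental SES carries a genomic component: parents' genomes shape the SES
environment they provide, and children share about half of the parental
allele pool. A regression of the phenotype on parental SES alone therefore
overstates the environmental SES effect, and a regression on the offspring
polygenic score alone overstates the direct genetic effect. This module
implements the coefficient-reduction accounting, the ×2 genomic-nurture
correction

    enviSES = ParentalSES − 2 · (reduction of the SES effect when the
                                 offspring PGS enters the model)

— motivated by the two genomic subcomponents of parental SES (shared and
non-shared with the child) being of about equal size — and the incremental-R²
ledger that splits explained variance into offspring-genome,
genomic-in-parental-SES and environmental-SES contributions, with the
genomic-in-SES term bounded above by the net-PGS incremental R².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "coefficient_reduction",
    "envses_correction",
    "incremental_r2",
    "DecompositionLedger",
    "build_ledger",
    "build_ledger_from_fits",
]


def coefficient_reduction(effect_without: float, effect_with: float) -> float:
    """Percent reduction of an effect when the other predictor block enters.

    100 · (effect_without − effect_with) / effect_without, sign-preserving
    (a coefficient that grows gives a negative reduction).
    """
    if effect_without == 0:
        raise ValueError("zero baseline effect: percent reduction undefined")
    return 100.0 * (effect_without - effect_with) / effect_without


def envses_correction(parental_ses_effect: float, reduced_amount: float):
    """The ×2 genomic-nurture correction of a parental-SES coefficient.

    ``parental_ses_effect`` is the estimate from a model without the
    offspring PGS; ``reduced_amount`` is how much that estimate shrinks when
    the PGS is added. Because the shrinkage removes only the half of the
    genomic component shared with the child, the full genomic contribution is
    taken as twice the shrinkage:

        enviSES       = parental_ses_effect − 2 · reduced_amount
        genomic share = 2 · reduced_amount / parental_ses_effect

    Returns ``(envses, genomic_share_pct)``.
    """
    for name, v in (("parental_ses_effect", parental_ses_effect),
                    ("reduced_amount", reduced_amount)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    envses = parental_ses_effect - 2.0 * reduced_amount
    if parental_ses_effect == 0:
        share = float("nan")
    else:
        share = 100.0 * 2.0 * reduced_amount / parental_ses_effect
    return envses, share


def incremental_r2(r2_larger_model: float, r2_smaller_model: float) -> float:
    """R² gain of the larger (nested-above) model; negative gains raise."""
    diff = r2_larger_model - r2_smaller_model
    if diff < -1e-12:
        raise ValueError(
            "nesting violation: larger model has smaller R² "
            f"({r2_larger_model} < {r2_smaller_model})"
        )
    return float(max(diff, 0.0))


def _infer_scale(values) -> str:
    """'percent' if the R² inputs exceed 1, else 'proportion'; mixing raises.

    A sub-1 value alongside super-1 values is ambiguous (it could be a small
    percentage or a proportion) and is rejected rather than guessed.
    """
    vals = [v for v in values if np.isfinite(v)]
    if any(v > 1.0 for v in vals):
        if any(v <= 1.0 for v in vals):
            raise ValueError(
                "mixed percent/proportion R² inputs; supply all on one scale"
            )
        return "percent"
    return "proportion"


@dataclass
class DecompositionLedger:
    """The incremental-R² partition and coefficient-reduction accounting.

    All R² fields share one scale (percent or proportion, inferred from the
    inputs). Identities hold exactly:

        net_pgs_r2        = r2_full − r2_ses_pc
        ses_incremental_r2 = r2_full − r2_pgs_pc
        env_ses_r2        = ses_incremental_r2 − genomic_in_ses_bound
        total_genomic_r2  = net_pgs_r2 + genomic_in_ses_bound

    ``genomic_in_ses_bound`` defaults to the net-PGS incremental R² (the
    upper-bound rule); it is surfaced separately so a user can substitute
    another bound.
    """

    r2_full: float
    r2_ses_pc: float
    r2_pgs_pc: float
    net_pgs_r2: float
    ses_incremental_r2: float
    genomic_in_ses_bound: float
    env_ses_r2: float
    total_genomic_r2: float
    scale: str
    reductions: pd.DataFrame = field(default_factory=pd.DataFrame)
    envses_effects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        assert abs(self.net_pgs_r2 - (self.r2_full - self.r2_ses_pc)) < 1e-12
        assert abs(self.ses_incremental_r2 - (self.r2_full - self.r2_pgs_pc)) < 1e-12
        assert abs(
            self.env_ses_r2 + self.genomic_in_ses_bound - self.ses_incremental_r2
        ) < 1e-12
        assert abs(
            self.total_genomic_r2 - (self.net_pgs_r2 + self.genomic_in_ses_bound)
        ) < 1e-12

    def to_dict(self) -> dict:
        return {
            "r2_full": self.r2_full,
            "r2_ses_pc": self.r2_ses_pc,
            "r2_pgs_pc": self.r2_pgs_pc,
            "net_pgs_r2": self.net_pgs_r2,
            "ses_incremental_r2": self.ses_incremental_r2,
            "genomic_in_ses_bound": self.genomic_in_ses_bound,
            "env_ses_r2": self.env_ses_r2,
            "total_genomic_r2": self.total_genomic_r2,
            "scale": self.scale,
            "reductions": self.reductions.to_dict(orient="records"),
            "envses_effects": self.envses_effects.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DecompositionLedger":
        return cls(
            r2_full=d["r2_full"],
            r2_ses_pc=d["r2_ses_pc"],
            r2_pgs_pc=d["r2_pgs_pc"],
            net_pgs_r2=d["net_pgs_r2"],
            ses_incremental_r2=d["ses_incremental_r2"],
            genomic_in_ses_bound=d["genomic_in_ses_bound"],
            env_ses_r2=d["env_ses_r2"],
            total_genomic_r2=d["total_genomic_r2"],
            scale=d["scale"],
            reductions=pd.DataFrame(d.get("reductions", [])),
            envses_effects=pd.DataFrame(d.get("envses_effects", [])),
        )

    def report(self) -> str:
        """Human-readable partition table."""
        unit = "%" if self.scale == "percent" else ""
        lines = [
            "Incremental-R2 decomposition",
            "-" * 44,
            f"  full model R2                 {self.r2_full:.4g}{unit}",
            f"  SES + PCs model R2            {self.r2_ses_pc:.4g}{unit}",
            f"  PGS + PCs model R2            {self.r2_pgs_pc:.4g}{unit}",
            f"  offspring genome (net PGS)    {self.net_pgs_r2:.4g}{unit}",
            f"  genomic in parental SES (<=)  {self.genomic_in_ses_bound:.4g}{unit}",
            f"  environmental parental SES    {self.env_ses_r2:.4g}{unit}",
            f"  total genomic                 {self.total_genomic_r2:.4g}{unit}",
            f"  total environmental           {self.env_ses_r2:.4g}{unit}",
        ]
        if len(self.reductions):
            lines += ["", "Coefficient reductions (%, without -> with the other block)"]
            for _, row in self.reductions.iterrows():
                lines.append(
                    f"  {row['term']:<28s} {row['effect_without']: .3f} -> "
                    f"{row['effect_with']: .3f}  ({row['reduction_pct']:.1f}%)"
                )
        return "\n".join(lines)


def build_ledger(
    r2_full: float,
    r2_ses_pc: float,
    r2_pgs_pc: float,
    ses_coef_pairs: dict | None = None,
    pgs_coef_pairs: dict | None = None,
    genomic_in_ses_bound: float | None = None,
) -> DecompositionLedger:
    """Assemble the decomposition ledger from three nested model R²s.

    ``r2_full`` is the SES + PGS + ancestry-PC model, ``r2_ses_pc`` drops the
    PGSs, ``r2_pgs_pc`` drops the SES block. Coefficient pairs map term name
    to ``(effect_without, effect_with)`` the other block; SES pairs also get
    an enviSES-corrected effect. The genomic-in-SES bound defaults to the
    net-PGS incremental R² (upper-bound rule).
    """
    scale = _infer_scale([r2_full, r2_ses_pc, r2_pgs_pc])
    net_pgs = incremental_r2(r2_full, r2_ses_pc)
    ses_incr = incremental_r2(r2_full, r2_pgs_pc)
    bound = net_pgs if genomic_in_ses_bound is None else float(genomic_in_ses_bound)
    env_ses = ses_incr - bound
    total_genomic = net_pgs + bound

    rows = []
    env_rows = []
    for term, (without, with_) in (ses_coef_pairs or {}).items():
        rows.append(
            {
                "term": term,
                "block": "ses",
                "effect_without": without,
                "effect_with": with_,
                "reduction_pct": coefficient_reduction(without, with_),
            }
        )
        envses, share = envses_correction(without, without - with_)
        env_rows.append(
            {"term": term, "envses_effect": envses, "genomic_share_pct": share}
        )
    for term, (without, with_) in (pgs_coef_pairs or {}).items():
        rows.append(
            {
                "term": term,
                "block": "pgs",
                "effect_without": without,
                "effect_with": with_,
                "reduction_pct": coefficient_reduction(without, with_),
            }
        )

    ledger = DecompositionLedger(
        r2_full=float(r2_full),
        r2_ses_pc=float(r2_ses_pc),
        r2_pgs_pc=float(r2_pgs_pc),
        net_pgs_r2=net_pgs,
        ses_incremental_r2=ses_incr,
        genomic_in_ses_bound=bound,
        env_ses_r2=env_ses,
        total_genomic_r2=total_genomic,
        scale=scale,
        reductions=pd.DataFrame(rows),
        envses_effects=pd.DataFrame(env_rows),
    )
    if genomic_in_ses_bound is None:
        ledger.validate()
    return ledger


def build_ledger_from_fits(fit_full, fit_ses_pc, fit_pgs_pc,
                           ses_terms=(), pgs_terms=()) -> DecompositionLedger:
    """Ledger from three :class:`~gnurture.mlmfit.ModelFit` objects.

    Uses each fit's companion OLS R² (proportion scale) and pairs
    coefficients for every requested SES and PGS term present in both
    relevant fits.
    """
    if not (fit_full.n_obs == fit_ses_pc.n_obs == fit_pgs_pc.n_obs):
        raise ValueError("the three fits must share the same data")
    ses_pairs = {
        t: (float(fit_ses_pc.params[t]), float(fit_full.params[t]))
        for t in ses_terms
        if t in fit_ses_pc.params.index and t in fit_full.params.index
    }
    pgs_pairs = {
        t: (float(fit_pgs_pc.params[t]), float(fit_full.params[t]))
        for t in pgs_terms
        if t in fit_pgs_pc.params.index and t in fit_full.params.index
    }
    return build_ledger(
        fit_full.ols_r2,
        fit_ses_pc.ols_r2,
        fit_pgs_pc.ols_r2,
        ses_coef_pairs=ses_pairs,
        pgs_coef_pairs=pgs_pairs,
    )
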