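"""Closed-form study arithmetic: lipopolyplex formulation, ELISpot responder
calls and rates, and tumor-burden summaries.

The lipopolyplex (LPP) is a core-shell nanoparticle: an mRNA/protamine
polyplex core (mRNA:protamine 5:1 v/v) wrapped in a four-lipid shell
(ionizable lipid : DOPE : cholesterol : mPEG-DMG at 40 : 15 : 43.5 : 1.5
mol%), mixed with the aqueous phase 3:1 aqueous:ethanol, at an
amine-to-phosphate (N:P) ratio of 4.8:1.  Given an mRNA mass the recipe
calculator emits per-component amounts such that recomputing N:P and the
mole fractions from the emitted masses reproduces the configured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ElispotRow, ValidationError

LIPID_COMPONENTS = ("ionizable", "dope", "cholesterol", "mpeg_dmg")
DEFAULT_MOLE_FRACTIONS = {
    "ionizable": 40.0,
    "dope": 15.0,
    "cholesterol": 43.5,
    "mpeg_dmg": 1.5,
}


@dataclass(frozen=True)
class FormulationConfig:
    """Molar masses and mixing constants of one batch recipe.

    The ionizable lipid is proprietary, so its molar mass must be supplied;
    ``example_formulation_config`` provides a synthetic fixture value.  DOPE,
    cholesterol and mPEG-DMG masses default to their catalog values.
    ``mean_nt_mw`` is the average molar mass per nucleotide of the mRNA
    (g/mol), ``amines_per_ionizable`` the number of ionizable amines per
    lipid molecule.
    """

    ionizable_mw: float
    dope_mw: float = 744.03
    cholesterol_mw: float = 386.65
    mpeg_dmg_mw: float = 2509.2
    mean_nt_mw: float = 330.0
    amines_per_ionizable: float = 1.0
    np_ratio: float = 4.8
    mole_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOLE_FRACTIONS)
    )
    mrna_protamine_vol_ratio: float = 5.0  # mRNA : protamine, v/v
    aqueous_ethanol_vol_ratio: float = 3.0
    mrna_conc_ug_per_ul: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ionizable_mw", "dope_mw", "cholesterol_mw", "mpeg_dmg_mw",
                     "mean_nt_mw"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        total = sum(self.mole_fractions[c] for c in LIPID_COMPONENTS)
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(
                f"lipid mole fractions must sum to 100, got {total}"
            )

    def mw(self, component: str) -> float:
        return {
            "ionizable": self.ionizable_mw,
            "dope": self.dope_mw,
            "cholesterol": self.cholesterol_mw,
            "mpeg_dmg": self.mpeg_dmg_mw,
        }[component]


def example_formulation_config() -> FormulationConfig:
    """Default config with a synthetic ionizable-lipid molar mass (710 g/mol,
    a typical magnitude for this lipid class; the real lipid is unnamed)."""
    return FormulationConfig(ionizable_mw=710.0)


@dataclass(frozen=True)
class LppRecipe:
    mrna_mass_ug: float
    phosphate_umol: float
    component_umol: dict[str, float]
    component_masses_ug: dict[str, float]
    mrna_volume_ul: float
    protamine_volume_ul: float
    ethanol_volume_ul: float
    config: FormulationConfig

    def recomputed_np_ratio(self) -> float:
        """N:P back-computed from the emitted ionizable mass and mRNA mass."""
        ion_umol = self.component_masses_ug["ionizable"] / self.config.ionizable_mw
        phosphate = self.mrna_mass_ug / self.config.mean_nt_mw
        return ion_umol * self.config.amines_per_ionizable / phosphate

    def recomputed_mole_fractions(self) -> dict[str, float]:
        """Mole percents back-computed from the emitted component masses."""
        umol = {
            c: self.component_masses_ug[c] / self.config.mw(c)
            for c in LIPID_COMPONENTS
        }
        total = sum(umol.values())
        return {c: 100.0 * v / total for c, v in umol.items()}


def lpp_recipe(mrna_mass_ug: float, config: FormulationConfig) -> LppRecipe:
    """Per-batch component amounts from mRNA mass, N:P ratio and lipid mole
    fractions.  Masses scale linearly through zero."""
    if mrna_mass_ug < 0:
        raise ValidationError("mRNA mass must be non-negative")
    phosphate_umol = mrna_mass_ug / config.mean_nt_mw
    ionizable_umol = config.np_ratio * phosphate_umol / config.amines_per_ionizable
    fr = config.mole_fractions
    component_umol = {
        c: ionizable_umol * fr[c] / fr["ionizable"] for c in LIPID_COMPONENTS
    }
    component_masses = {c: component_umol[c] * config.mw(c) for c in LIPID_COMPONENTS}
    mrna_volume = mrna_mass_ug / config.mrna_conc_ug_per_ul
    protamine_volume = mrna_volume / config.mrna_protamine_vol_ratio
    ethanol_volume = (mrna_volume + protamine_volume) / config.aqueous_ethanol_vol_ratio
    return LppRecipe(
        mrna_mass_ug=mrna_mass_ug,
        phosphate_umol=phosphate_umol,
        component_umol=component_umol,
        component_masses_ug=component_masses,
        mrna_volume_ul=mrna_volume,
        protamine_volume_ul=protamine_volume,
        ethanol_volume_ul=ethanol_volume,
        config=config,
    )


# ---------------------------------------------------------------------------
# ELISpot

@dataclass(frozen=True)
class ResponderRule:
    """Responder iff mean >= fold_threshold x negative-control mean AND
    background-subtracted spots >= absolute_threshold.  A standard ELISpot
    convention; the thresholds are configurable and echoed in each call."""

    fold_threshold: float = 2.0
    absolute_threshold: float = 10.0


@dataclass(frozen=True)
class ResponderCall:
    peptide_id: str
    group: str
    mean_spots: float
    neg_control_mean: float
    normalized_spots: float
    is_responder: bool
    rule: ResponderRule


def call_responders(
    rows: Sequence[ElispotRow], rule: ResponderRule | None = None
) -> list[ResponderCall]:
    """Per-peptide responder calls from replicate spot counts.

    Means are taken over replicates; normalized spots are max(0, mean - the
    group's negative-control mean).  Positive-control rows are excluded from
    peptide calls.  Missing negative controls raise, naming the group.
    """
    rule = rule or ResponderRule()
    groups = sorted({r.group for r in rows})
    calls: list[ResponderCall] = []
    for g in groups:
        grows = [r for r in rows if r.group == g]
        negs = [r.spot_count for r in grows if r.is_negative_control]
        if not negs:
            raise ValidationError(f"group {g!r} has no negative-control rows")
        neg_mean = float(np.mean(negs))
        peptides = sorted(
            {
                r.peptide_id
                for r in grows
                if not r.is_negative_control and not r.is_positive_control
            }
        )
        for pid in peptides:
            counts = [
                r.spot_count
                for r in grows
                if r.peptide_id == pid
                and not r.is_negative_control
                and not r.is_positive_control
            ]
            mean = float(np.mean(counts))
            normalized = max(0.0, mean - neg_mean)
            responder = (
                mean >= rule.fold_threshold * neg_mean
                and normalized >= rule.absolute_threshold
            )
            calls.append(
                ResponderCall(
                    peptide_id=pid,
                    group=g,
                    mean_spots=mean,
                    neg_control_mean=neg_mean,
                    normalized_spots=normalized,
                    is_responder=responder,
                    rule=rule,
                )
            )
    return calls


def responder_rate(
    n_resp: int, n_eval: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Responder percentage (one decimal) with an exact Clopper-Pearson CI.

    Returns ``(percent, (lo_percent, hi_percent))``.
    """
    if n_eval < 1:
        raise ValidationError("n_eval must be >= 1")
    if not 0 <= n_resp <= n_eval:
        raise ValidationError(f"need 0 <= n_resp <= n_eval, got {n_resp}/{n_eval}")
    pct = round(100.0 * n_resp / n_eval, 1)
    alpha = 1.0 - confidence
    lo = 0.0 if n_resp == 0 else float(stats.beta.ppf(alpha / 2, n_resp, n_eval - n_resp + 1))
    hi = 1.0 if n_resp == n_eval else float(
        stats.beta.ppf(1 - alpha / 2, n_resp + 1, n_eval - n_resp)
    )
    return pct, (100.0 * lo, 100.0 * hi)


# ---------------------------------------------------------------------------
# tumor burden

def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume V = 1/2 * L * W^2 (mm^3); swaps L/W if given reversed."""
    if length_mm < 0 or width_mm < 0:
        raise ValidationError("tumor dimensions must be non-negative")
    if width_mm > length_mm:
        import warnings

        warnings.warn(
            "width > length; swapping per caliper convention", stacklevel=2
        )
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


def tgi(mean_treated: float, mean_control: float) -> float:
    """Tumor growth inhibition, percent: 100 * (1 - T/C) on group means."""
    if mean_control <= 0:
        raise ValidationError("control mean must be positive")
    if mean_treated < 0:
        raise ValidationError("treated mean must be non-negative")
    return 100.0 * (1.0 - mean_treated / mean_control)
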