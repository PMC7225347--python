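"""Efficiency-corrected relative expression (Pfaffl method).

The ratio of a target gene between a sample and a calibrator condition,
normalised to a reference gene, is

    ratio = E_target**dCq_target / E_ref**dCq_ref

with E the fold-amplification per cycle (1 + %E/100) and
dCq = mean Cq(calibrator) - Cq(sample), so higher expression gives a ratio
above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: primer efficiencies used for the yeast PMC1/ACT1 assay (percent)
DEFAULT_EFFICIENCIES = {"PMC1": 85.0, "ACT1": 91.0}


@dataclass(frozen=True)
class PrimerEfficiency:
    gene: str
    percent_e: float

    def __post_init__(self) -> None:
        if not 0 < self.percent_e <= 100:
            raise ValueError("percent_e must lie in (0, 100]")

    @property
    def e_factor(self) -> float:
        """Fold amplification per cycle."""
        return 1.0 + self.percent_e / 100.0


def efficiency(percent_e: float, gene: str = "") -> PrimerEfficiency:
    """Primer efficiency from its percent value (100% -> perfect doubling)."""
    return PrimerEfficiency(gene=gene, percent_e=percent_e)


def pfaffl_ratio(
    e_target: PrimerEfficiency | float,
    dcq_target: float,
    e_ref: PrimerEfficiency | float,
    dcq_ref: float,
) -> float:
    """Efficiency-corrected fold change E_t**dCq_t / E_r**dCq_r.

    dCq follows the convention mean Cq(calibrator) - Cq(sample).
    """
    et = e_target.e_factor if isinstance(e_target, PrimerEfficiency) else float(e_target)
    er = e_ref.e_factor if isinstance(e_ref, PrimerEfficiency) else float(e_ref)
    if et <= 1 or er <= 1:
        raise ValueError("amplification factors must exceed 1")
    return et**dcq_target / er**dcq_ref


@dataclass
class QpcrPlate:
    """Long-format Cq plate: one row per (condition, gene, replicate)."""

    data: pd.DataFrame
    reference_gene: str
    calibrator_condition: str

    def __post_init__(self) -> None:
        required = {"condition", "gene", "replicate", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table lacks columns {sorted(missing)}")
        present = self.data.dropna(subset=["cq"])
        if np.any(present["cq"] <= 0):
            raise ValueError("Cq values must be positive")
        if self.calibrator_condition not in set(self.data["condition"]):
            raise ValueError(
                f"calibrator condition {self.calibrator_condition!r} absent from plate"
            )
        for cond, sub in present.groupby("condition"):
            if self.reference_gene not in set(sub["gene"]):
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing for "
                    f"condition {cond!r}"
                )

    def cq_values(self, condition: str, gene: str) -> np.ndarray:
        mask = (self.data["condition"] == condition) & (self.data["gene"] == gene)
        return self.data.loc[mask, "cq"].to_numpy(dtype=float)


def relative_expression(
    plate: QpcrPlate, efficiencies: dict[str, float] | list[PrimerEfficiency] | None = None
) -> pd.DataFrame:
    """Mean +/- SD Pfaffl ratio per condition and target gene.

    Replicates are unpaired: each replicate's dCq is taken against the
    calibrator-condition mean Cq.  The condition mean ratio is computed from
    the condition-mean Cq values (so the calibrator is exactly 1); the SD is
    the spread of the per-replicate ratios.  Conditions whose target Cq
    values are all missing are reported non-detectable (``nd`` = True).
    """
    if efficiencies is None:
        efficiencies = dict(DEFAULT_EFFICIENCIES)
    if isinstance(efficiencies, dict):
        eff = {g: efficiency(p, g) for g, p in efficiencies.items()}
    else:
        eff = {e.gene: e for e in efficiencies}

    genes = [g for g in plate.data["gene"].unique() if g != plate.reference_gene]
    for gene in genes:
        if gene not in eff:
            raise ValueError(f"no primer efficiency supplied for gene {gene!r}")
    if plate.reference_gene not in eff:
        raise ValueError(f"no primer efficiency supplied for {plate.reference_gene!r}")
    e_ref = eff[plate.reference_gene]

    rows = []
    for gene in genes:
        e_t = eff[gene]
        cal_t = plate.cq_values(plate.calibrator_condition, gene)
        cal_r = plate.cq_values(plate.calibrator_condition, plate.reference_gene)
        cal_t_mean = np.nanmean(cal_t)
        cal_r_mean = np.nanmean(cal_r)
        for cond in plate.data["condition"].unique():
            cq_t = plate.cq_values(cond, gene)
            cq_r = plate.cq_values(cond, plate.reference_gene)
            detectable_t = cq_t[~np.isnan(cq_t)]
            if detectable_t.size == 0:
                rows.append(
                    {
                        "condition": cond,
                        "target_gene": gene,
                        "mean_ratio": np.nan,
                        "sd_ratio": np.nan,
                        "n": 0,
                        "nd": True,
                    }
                )
                continue
            mean_ratio = pfaffl_ratio(
                e_t,
                cal_t_mean - np.nanmean(cq_t),
                e_ref,
                cal_r_mean - np.nanmean(cq_r),
            )
            n = min(detectable_t.size, cq_r[~np.isnan(cq_r)].size)
            rep_ratios = [
                pfaffl_ratio(e_t, cal_t_mean - cq_t[i], e_ref, cal_r_mean - cq_r[i])
                for i in range(n)
            ]
            sd = float(np.std(rep_ratios, ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    "condition": cond,
                    "target_gene": gene,
                    "mean_ratio": float(mean_ratio),
                    "sd_ratio": sd,
                    "n": n,
                    "nd": False,
                }
            )
    return pd.DataFrame(rows)
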