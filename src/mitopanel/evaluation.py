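"""Imputation accuracy evaluation.

Genotype concordance is measured per site with the Matthews
correlation coefficient (MCC), treating the site's (biallelic-
collapsed) alternate allele as the positive class:

    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 whenever a factor of the denominator is zero.
Site-level MCCs are summarised by their mean with a normal-
approximation 95% confidence interval.  Haplogroup accuracy is the
fraction of samples whose called label matches the truth label, at the
full-label or macrohaplogroup level, before (masked) and after
imputation; unassigned calls count as discordant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip_sim import ChipDefinition, TypedGenotypes, mask_to_chip
from .haplogroup import HaplogroupCall, HaplogroupTable, call_haplogroup, macro_collapse
from .imputation import (
    HaplotypeImputer,
    ImputationResult,
    MajorAlleleImputer,
)
from .panel import MISSING, VariantPanel

Z_95 = 1.959963984540054


@dataclass
class SiteConfusion:
    """Confusion counts at one site (alt allele = positive class)."""

    position: int
    tp: int
    fp: int
    tn: int
    fn: int
    n_missing_excluded: int

    @property
    def mcc(self) -> float:
        return mcc_from_counts(self.tp, self.fp, self.tn, self.fn)


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC from confusion counts; 0 when any denominator factor is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def per_site_mcc(
    truth: VariantPanel,
    result: ImputationResult,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site confusion counts and MCC for imputed sites.

    Only sites that were imputed (not chip-typed) and passed the info
    filter are evaluated, intersected with the truth panel's sites (and
    with *positions* if given).  Truth entries missing for a sample are
    excluded from that site's counts.
    """
    missing_targets = [s for s in result.sample_ids if s not in truth.sample_ids]
    if missing_targets:
        raise ValueError(f"result samples absent from truth panel: {missing_targets}")
    truth_sub = truth.subset_samples(list(result.sample_ids))
    truth_pos = truth_sub.position_index()
    eval_sites = result.imputed_sites
    rows = []
    for i in np.flatnonzero(eval_sites):
        pos = int(result.positions[i])
        if pos not in truth_pos:
            continue
        if positions is not None and pos not in positions:
            continue
        t = truth_pos[pos]
        alt = result.alt_alleles[i]
        truth_alleles = truth_sub.site_alleles(t)
        truth_codes = truth_sub.haplotypes[t]
        observed = truth_codes != MISSING
        truth_is_alt = np.zeros(truth_sub.n_samples, dtype=bool)
        for code, base in enumerate(truth_alleles):
            if base == alt:
                truth_is_alt |= truth_codes == code
        call_is_alt = result.hard_calls[i] == 1
        tp = int(np.sum(observed & truth_is_alt & call_is_alt))
        fp = int(np.sum(observed & ~truth_is_alt & call_is_alt))
        tn = int(np.sum(observed & ~truth_is_alt & ~call_is_alt))
        fn = int(np.sum(observed & truth_is_alt & ~call_is_alt))
        conf = SiteConfusion(
            position=pos, tp=tp, fp=fp, tn=tn, fn=fn,
            n_missing_excluded=int(np.sum(~observed)),
        )
        rows.append(
            {
                "position": pos, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
                "n_missing_excluded": conf.n_missing_excluded, "mcc": conf.mcc,
            }
        )
    if not rows:
        warnings.warn("no overlapping imputed sites to evaluate")
        return pd.DataFrame(
            columns=["position", "TP", "FP", "TN", "FN", "n_missing_excluded", "mcc"]
        )
    return pd.DataFrame(rows)


def mean_mcc_ci(mccs) -> tuple[float, float, float]:
    """Mean site-level MCC with a normal-approximation 95% CI."""
    mccs = np.asarray(mccs, dtype=float)
    if mccs.size == 0:
        raise ValueError("cannot summarise an empty set of MCC values")
    mu = float(mccs.mean())
    if mccs.size == 1:
        return mu, mu, mu
    se = float(mccs.std(ddof=1) / np.sqrt(mccs.size))
    return mu, mu - Z_95 * se, mu + Z_95 * se


def haplogroup_concordance(
    truth_calls: dict[str, HaplogroupCall | str],
    test_calls: dict[str, HaplogroupCall | str],
    level: str = "macro",
) -> float:
    """Fraction of samples with matching haplogroup labels.

    ``level`` is ``"macro"`` (labels macro-collapsed first) or
    ``"full"``.  Unassigned test calls count as discordant.
    """
    if level not in ("macro", "full"):
        raise ValueError("level must be 'macro' or 'full'")
    common = sorted(set(truth_calls) & set(test_calls))
    if not common:
        raise ValueError("truth and test calls share no samples")

    def _label(call) -> str | None:
        label = call.label if isinstance(call, HaplogroupCall) else call
        if label is None:
            return None
        return macro_collapse(label) if level == "macro" else label

    n_match = sum(
        1
        for s in common
        if _label(truth_calls[s]) is not None
        and _label(truth_calls[s]) == _label(test_calls[s])
    )
    return n_match / len(common)


@dataclass
class EvaluationReport:
    """Full accuracy report for one imputation run."""

    site_mcc: pd.DataFrame
    mu_mcc: float
    mcc_ci: tuple[float, float]
    concordance: dict[str, float]  # keys like "masked_macro", "imputed_full"

    @property
    def improvement_macro(self) -> float:
        return self.concordance["imputed_macro"] - self.concordance["masked_macro"]

    @property
    def improvement_full(self) -> float:
        return self.concordance["imputed_full"] - self.concordance["masked_full"]


def evaluate_run(
    truth: VariantPanel,
    truth_labels: dict[str, str],
    typed: TypedGenotypes,
    result: ImputationResult,
    table: HaplogroupTable,
    min_score: float = 0.9,
) -> EvaluationReport:
    """Per-site MCC plus haplogroup concordance before/after imputation."""
    site_mcc = per_site_mcc(truth, result)
    if len(site_mcc):
        mu, lo, hi = mean_mcc_ci(site_mcc["mcc"].to_numpy())
    else:
        mu, lo, hi = float("nan"), float("nan"), float("nan")
    masked_calls = {
        sid: call_haplogroup(typed.allele_map(sid), table, sid, min_score)
        for sid in typed.sample_ids
    }
    imputed_calls = {
        sid: call_haplogroup(result.allele_map(sid), table, sid, min_score)
        for sid in result.sample_ids
    }
    concordance = {
        f"{stage}_{level}": haplogroup_concordance(truth_labels, calls, level)
        for stage, calls in (("masked", masked_calls), ("imputed", imputed_calls))
        for level in ("macro", "full")
    }
    return EvaluationReport(
        site_mcc=site_mcc, mu_mcc=mu, mcc_ci=(lo, hi), concordance=concordance
    )


def baseline_mean_mcc(
    truth: VariantPanel,
    reference: VariantPanel,
    typed: TypedGenotypes,
    positions: np.ndarray | None = None,
) -> float:
    """Mean per-site MCC of the frequency-only baseline imputer."""
    baseline = MajorAlleleImputer().fit(reference).predict(typed)
    table = per_site_mcc(truth, baseline, positions=positions)
    if not len(table):
        return float("nan")
    return float(table["mcc"].mean())


def parameter_sweep(
    truth: VariantPanel,
    truth_labels: dict[str, str],
    chips: list[ChipDefinition],
    target_ids: list[str],
    table: HaplogroupTable,
    k_hap_grid=(100, 250, 500, 1000),
    maf_grid=(0.01, 0.005, 0.001),
    copying_error: float | str = "auto",
    info_threshold: float = 0.3,
    min_score: float = 0.9,
) -> pd.DataFrame:
    """Run the imputation pipeline over a (chip, k_hap, MAF) grid.

    Returns one long-format row per combination with the mean MCC, mean
    info score of imputed sites, and haplogroup concordances.  The
    pipeline is fully deterministic given its inputs.
    """
    if not chips or not len(k_hap_grid) or not len(maf_grid):
        raise ValueError("chips, k_hap_grid and maf_grid must be non-empty")
    reference_ids = [s for s in truth.sample_ids if s not in set(target_ids)]
    reference = truth.subset_samples(reference_ids)
    rows = []
    for chip, k_hap, maf in itertools.product(chips, k_hap_grid, maf_grid):
        typed = mask_to_chip(truth, chip, target_ids)
        imputer = HaplotypeImputer(
            k_hap=k_hap,
            copying_error=copying_error,
            info_threshold=info_threshold,
            maf_threshold=maf,
        )
        result = imputer.fit(reference).predict(typed)
        report = evaluate_run(truth, truth_labels, typed, result, table, min_score)
        imputed = result.imputed_sites
        rows.append(
            {
                "chip": chip.chip_name,
                "k_hap": k_hap,
                "maf": maf,
                "n_panel_sites": result.n_sites,
                "n_imputed_sites": int(imputed.sum()),
                "mu_mcc": report.mu_mcc,
                "mcc_ci_lo": report.mcc_ci[0],
                "mcc_ci_hi": report.mcc_ci[1],
                "mean_info": float(result.info[imputed].mean()) if imputed.any() else float("nan"),
                **report.concordance,
            }
        )
    return pd.DataFrame(rows)
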