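"""Haploid copying-model imputation of mitochondrial variants.

The mitochondrial genome is haploid and effectively non-recombining, so
an imputation protocol that fixes the recombination rate to zero at
every site collapses the Li–Stephens haplotype-copying HMM to a
single-template mixture: a target haplotype is modelled as one entire
reference haplotype copied with an independent per-site error
probability ``lambda``.  The posterior weight of reference haplotype
*h* given the target's typed alleles is then a simple product over the
mutually non-missing typed sites,

    w_h  ∝  Π_s (1 - lambda)^[match]  ·  lambda^[mismatch],

and the posterior probability of the alternate allele at an untyped
site s is

    P(alt at s)  =  Σ_h w_h · [ (1 - lambda)·1(h_s = alt) + lambda·1(h_s = ref) ],

with haplotypes missing at s dropped and the weights renormalised over
the remainder.  No forward–backward pass and no MCMC are needed; the
computation is exact.

Conditioning-set selection mirrors the ``k_hap`` parameter of standard
imputation software: for each target only the ``k_hap`` reference
haplotypes closest in Hamming distance over the typed sites are used.

Per-site certainty is summarised by the haploid info score

    info = 1 - Σ_i p_i (1 - p_i) / (N · θ̂ (1 - θ̂)),    θ̂ = mean(p),

which is 1 for fully certain posteriors and 0 when imputation adds
nothing beyond the allele frequency; imputed sites with info ≤ 0.3 are
filtered by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .chip_sim import MISSING_CHAR, TypedGenotypes
from .panel import MISSING, VariantPanel, filter_maf

DEFAULT_INFO_THRESHOLD = 0.3
DEFAULT_K_HAP = 500

#: k_hap grid conventionally swept when tuning.
K_HAP_GRID = (100, 250, 500, 1000, 2500, 5000, 10000, 20000, 30000)
#: MAF thresholds conventionally swept when tuning (>1%, >0.5%, >0.1%).
MAF_GRID = (0.01, 0.005, 0.001)


def default_copying_error(k: int) -> float:
    """Default per-site copying-error rate for *k* conditioning haplotypes.

    Uses the Watterson-style population-scaled mutation rate
    ``theta = 1 / sum_{i=1}^{k-1} 1/i`` and sets
    ``lambda = theta / (2 (k + theta))``, which decreases as the
    conditioning set grows.  For ``k < 2`` the harmonic sum is empty
    and ``theta`` is taken as 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    theta = 1.0 / np.sum(1.0 / np.arange(1, k)) if k >= 2 else 1.0
    return float(theta / (2.0 * (k + theta)))


@dataclass
class ImputationConfig:
    """Imputation parameters."""

    k_hap: int = DEFAULT_K_HAP
    copying_error: float | str = "auto"
    info_threshold: float = DEFAULT_INFO_THRESHOLD
    maf_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.k_hap < 1:
            raise ValueError("k_hap must be >= 1")
        if not isinstance(self.copying_error, str):
            if not 0.0 < float(self.copying_error) < 0.5:
                raise ValueError("copying_error must lie in (0, 0.5)")
        if not 0.0 <= self.info_threshold < 1.0:
            raise ValueError("info_threshold must lie in [0, 1)")


@dataclass
class ImputationResult:
    """Posterior allele probabilities, hard calls and per-site info scores.

    Arrays are (n_sites, n_targets) over the reference panel's sites in
    panel order; ``p_alt`` is the posterior probability of the (single,
    biallelic-collapsed) alternate allele.
    """

    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    sample_ids: list[str]
    p_alt: np.ndarray
    typed_sites: np.ndarray      # (n_sites,) bool: site was on the chip
    observed_mask: np.ndarray    # (n_sites, n_targets) bool: allele observed
    info: np.ndarray             # (n_sites,) in [0, 1]
    filtered: np.ndarray         # (n_sites,) bool: failed the info filter
    hard_calls: np.ndarray       # (n_sites, n_targets) int8, 0=ref 1=alt
    freq_fallback: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.freq_fallback is None:
            self.freq_fallback = np.zeros(self.p_alt.shape, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_targets(self) -> int:
        return len(self.sample_ids)

    @property
    def imputed_sites(self) -> np.ndarray:
        """Sites that were imputed (not typed) and passed the info filter."""
        return ~self.typed_sites & ~self.filtered

    def allele_map(self, sample_id: str) -> dict[int, str]:
        """Position -> base for one sample: observed alleles at typed
        sites, hard calls at imputed sites passing the info filter."""
        j = self.sample_ids.index(sample_id)
        out: dict[int, str] = {}
        for i, pos in enumerate(self.positions):
            if self.filtered[i] and not self.typed_sites[i]:
                continue
            if self.typed_sites[i] and not self.observed_mask[i, j]:
                continue
            call = self.hard_calls[i, j]
            out[int(pos)] = self.alt_alleles[i] if call == 1 else self.ref_alleles[i]
        return out


def encode_targets(panel: VariantPanel, typed: TypedGenotypes) -> np.ndarray:
    """Map observed target alleles onto the panel's biallelic coding.

    Returns an (n_panel_sites, n_targets) int8 matrix: 1 where the
    observation equals the site's alternate allele, 0 for any other
    specified base (one-vs-rest, matching the panel collapse), and
    :data:`MISSING` at untyped sites and missing observations.
    """
    pos_index = panel.position_index()
    G = np.full((panel.n_sites, typed.n_samples), MISSING, dtype=np.int8)
    for t, pos in enumerate(typed.positions):
        i = pos_index.get(int(pos))
        if i is None:
            continue
        alt = panel.alt_alleles[i][0] if panel.alt_alleles[i] else None
        obs = typed.alleles[t]
        specified = obs != MISSING_CHAR
        G[i, specified] = 0
        if alt is not None:
            G[i, (obs == alt)] = 1
    return G


def select_conditioning_haplotypes(
    target: np.ndarray, panel: VariantPanel, k_hap: int
) -> np.ndarray:
    """Indices of the *k_hap* panel haplotypes nearest the target.

    Distance is the Hamming distance over sites typed in the target and
    non-missing in the haplotype; ties are broken by ascending panel
    index.  Returns all haplotypes when ``k_hap >= n_samples``.
    """
    if panel.n_samples == 0:
        raise ValueError("reference panel has no haplotypes")
    K = panel.n_samples
    if k_hap >= K:
        return np.arange(K)
    typed = target != MISSING
    H = panel.haplotypes[typed]
    g = target[typed][:, None]
    mismatch = ((H != g) & (H != MISSING)).sum(axis=0)
    order = np.argsort(mismatch, kind="stable")
    return np.sort(order[:k_hap])


def copying_weights(
    target: np.ndarray, haplotypes: np.ndarray, copying_error: float
) -> np.ndarray:
    """Normalised copying weight of each reference haplotype.

    ``haplotypes`` is (n_sites, K).  The weight of haplotype *h* is the
    product over typed, mutually non-missing sites of ``1 - lambda``
    for a match and ``lambda`` for a mismatch, accumulated in log space
    and normalised to sum to one.  With zero typed overlap everywhere
    the weights are uniform (the empty product).
    """
    lam = float(copying_error)
    if not 0.0 < lam < 0.5:
        raise ValueError("copying_error must lie in (0, 0.5)")
    typed = target != MISSING
    H = haplotypes[typed]
    g = target[typed][:, None]
    both = H != MISSING
    match = ((H == g) & both).sum(axis=0)
    mismatch = ((H != g) & both).sum(axis=0)
    logw = match * np.log1p(-lam) + mismatch * np.log(lam)
    logw -= logw.max() if logw.size else 0.0
    w = np.exp(logw)
    return w / w.sum()


def impute_sample(
    target: np.ndarray,
    panel: VariantPanel,
    config: ImputationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior P(alt) at every panel site for one target haplotype.

    Returns ``(p_alt, freq_fallback)``.  Typed sites get a degenerate
    posterior on the observed allele.  Reference haplotypes missing at
    a site are skipped with the weights renormalised among the
    carriers; if every conditioning haplotype is missing there, the
    panel allele frequency is used and the site flagged.
    """
    cond = select_conditioning_haplotypes(target, panel, config.k_hap)
    lam = (
        default_copying_error(len(cond))
        if isinstance(config.copying_error, str)
        else float(config.copying_error)
    )
    H = panel.haplotypes[:, cond]
    w = copying_weights(target, H, lam)

    present = H != MISSING
    wsum = present @ w
    walt = (H == 1) @ w
    p = np.empty(panel.n_sites)
    fallback = wsum <= 0.0
    ok = ~fallback
    p[ok] = lam + (1.0 - 2.0 * lam) * walt[ok] / wsum[ok]
    if fallback.any():
        freqs = _alt_frequencies(panel)
        p[fallback] = freqs[fallback]

    typed = target != MISSING
    p[typed] = (target[typed] == 1).astype(float)
    fallback[typed] = False
    return p, fallback


def _alt_frequencies(panel: VariantPanel) -> np.ndarray:
    H = panel.haplotypes
    nm = (H != MISSING).sum(axis=1)
    alt = (H == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f = np.where(nm > 0, alt / np.maximum(nm, 1), 0.5)
    return f


def info_score(p: np.ndarray) -> float:
    """Haploid info score of a site's posterior alt probabilities.

    ``1 - Σ p(1-p) / (N θ̂ (1-θ̂))`` with ``θ̂ = mean(p)``; defined as 1
    when θ̂ is 0 or 1 (a monomorphic, fully certain site) and clamped
    to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("info score undefined for zero samples")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    theta = p.mean()
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    score = 1.0 - np.sum(p * (1.0 - p)) / (p.size * theta * (1.0 - theta))
    return float(min(1.0, max(0.0, score)))


def hard_call(p_alt: float) -> int:
    """Argmax allele for a biallelic posterior; exact ties go to ref."""
    return 1 if p_alt > 0.5 else 0


def apply_info_filter(
    result: ImputationResult, threshold: float = DEFAULT_INFO_THRESHOLD
) -> ImputationResult:
    """Mark imputed sites with info score <= *threshold* as filtered.

    Typed sites are never filtered.
    """
    filtered = (result.info <= threshold) & ~result.typed_sites
    return dataclasses.replace(result, filtered=filtered)


class HaplotypeImputer(BaseEstimator):
    """Impute untyped mitochondrial sites from a haploid reference panel.

    A scikit-learn-style estimator: ``fit`` takes a
    :class:`~mitopanel.panel.VariantPanel` of reference haplotypes,
    ``predict`` takes :class:`~mitopanel.chip_sim.TypedGenotypes` for
    the target samples and returns an :class:`ImputationResult`.

    Parameters
    ----------
    k_hap : int
        Number of conditioning reference haplotypes per target.
    copying_error : float or "auto"
        Per-site copying-error probability in (0, 0.5); ``"auto"``
        derives it from the conditioning-set size
        (:func:`default_copying_error`).
    info_threshold : float
        Imputed sites with info score at or below this are filtered.
    maf_threshold : float or None
        If given, the reference panel is MAF-filtered (strict ``>``)
        before imputation.
    """

    def __init__(
        self,
        k_hap: int = DEFAULT_K_HAP,
        copying_error: float | str = "auto",
        info_threshold: float = DEFAULT_INFO_THRESHOLD,
        maf_threshold: float | None = None,
    ):
        self.k_hap = k_hap
        self.copying_error = copying_error
        self.info_threshold = info_threshold
        self.maf_threshold = maf_threshold

    def _config(self) -> ImputationConfig:
        return ImputationConfig(
            k_hap=self.k_hap,
            copying_error=self.copying_error,
            info_threshold=self.info_threshold,
            maf_threshold=self.maf_threshold,
        )

    def fit(self, panel: VariantPanel, y=None) -> "HaplotypeImputer":
        """Prepare the reference panel (MAF filter + biallelic collapse)."""
        config = self._config()  # validates parameters
        if panel.n_samples == 0:
            raise ValueError("reference panel has no haplotypes")
        if self.maf_threshold is not None:
            panel = filter_maf(panel, self.maf_threshold)
        self.panel_ = panel.to_biallelic()
        self.n_haplotypes_ = panel.n_samples
        self.n_sites_ = self.panel_.n_sites
        k = min(config.k_hap, self.n_haplotypes_)
        self.copying_error_ = (
            default_copying_error(k)
            if isinstance(config.copying_error, str)
            else float(config.copying_error)
        )
        return self

    def predict(self, typed: TypedGenotypes) -> ImputationResult:
        """Impute every panel site for every target sample."""
        if not hasattr(self, "panel_"):
            raise ValueError("HaplotypeImputer is not fitted yet")
        panel = self.panel_
        config = self._config()
        G = encode_targets(panel, typed)
        n_sites, n_targets = panel.n_sites, typed.n_samples
        p_alt = np.empty((n_sites, n_targets))
        fallback = np.zeros((n_sites, n_targets), dtype=bool)
        for j in range(n_targets):
            p_alt[:, j], fallback[:, j] = impute_sample(G[:, j], panel, config)
        typed_sites = np.isin(panel.positions, typed.positions)
        observed = G != MISSING
        info = np.array([info_score(p_alt[i]) for i in range(n_sites)])
        hard = (p_alt > 0.5).astype(np.int8)
        hard[observed] = G[observed]
        result = ImputationResult(
            positions=panel.positions.copy(),
            ref_alleles=list(panel.ref_alleles),
            alt_alleles=[a[0] if a else "." for a in panel.alt_alleles],
            sample_ids=list(typed.sample_ids),
            p_alt=p_alt,
            typed_sites=typed_sites,
            observed_mask=observed,
            info=info,
            filtered=np.zeros(n_sites, dtype=bool),
            hard_calls=hard,
            freq_fallback=fallback,
        )
        return apply_info_filter(result, config.info_threshold)

    def fit_predict(self, panel: VariantPanel, typed: TypedGenotypes) -> ImputationResult:
        return self.fit(panel).predict(typed)


class MajorAlleleImputer(BaseEstimator):
    """Frequency-only baseline: predict each site's panel allele frequency.

    Every untyped site gets posterior P(alt) equal to the reference
    panel's alternate-allele frequency for every target; hard calls are
    the panel major allele.  No info filtering is applied (the info
    score of a frequency-only posterior is 0 by construction), so the
    baseline remains comparable at every site.
    """

    def __init__(self, maf_threshold: float | None = None):
        self.maf_threshold = maf_threshold

    def fit(self, panel: VariantPanel, y=None) -> "MajorAlleleImputer":
        if self.maf_threshold is not None:
            panel = filter_maf(panel, self.maf_threshold)
        self.panel_ = panel.to_biallelic()
        self.alt_freq_ = _alt_frequencies(self.panel_)
        return self

    def predict(self, typed: TypedGenotypes) -> ImputationResult:
        if not hasattr(self, "panel_"):
            raise ValueError("MajorAlleleImputer is not fitted yet")
        panel = self.panel_
        G = encode_targets(panel, typed)
        n_sites, n_targets = panel.n_sites, typed.n_samples
        p_alt = np.tile(self.alt_freq_[:, None], (1, n_targets))
        observed = G != MISSING
        p_alt[observed] = G[observed].astype(float)
        typed_sites = np.isin(panel.positions, typed.positions)
        hard = (p_alt > 0.5).astype(np.int8)
        info = np.array([info_score(p_alt[i]) for i in range(n_sites)])
        return ImputationResult(
            positions=panel.positions.copy(),
            ref_alleles=list(panel.ref_alleles),
            alt_alleles=[a[0] if a else "." for a in panel.alt_alleles],
            sample_ids=list(typed.sample_ids),
            p_alt=p_alt,
            typed_sites=typed_sites,
            observed_mask=observed,
            info=info,
            filtered=np.zeros(n_sites, dtype=bool),
            hard_calls=hard,
        )


def result_to_panel(result: ImputationResult, include_filtered: bool = False) -> VariantPanel:
    """Hard calls of an imputation run as a :class:`VariantPanel`.

    Sites failing the info filter are dropped unless
    ``include_filtered`` is set; typed-but-unobserved entries carry the
    imputed call.
    """
    keep = np.ones(result.n_sites, dtype=bool) if include_filtered else ~result.filtered
    idx = np.flatnonzero(keep)
    return VariantPanel(
        positions=result.positions[idx],
        ref_alleles=[result.ref_alleles[i] for i in idx],
        alt_alleles=[
            (result.alt_alleles[i],) if result.alt_alleles[i] != "." else ()
            for i in idx
        ],
        haplotypes=result.hard_calls[idx].astype(np.int8),
        sample_ids=list(result.sample_ids),
    )
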