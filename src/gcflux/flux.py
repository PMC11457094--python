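"""Geometric tract-length model with detection correction.

True tract lengths are geometric: P(L = l) = (1 - phi) * phi**(l - 1), so the
mean length is 1 / (1 - phi) and phi is the probability that a conversion
tract extends by one more nucleotide.  Detection marks each nucleotide of a
true tract informative independently with probability psi_bar (the mean
per-site informativeness for the (region, donor, recipient) group); a tract
is observed only when at least two sites are informative, and the observed
span d is the distance between the outermost informative sites.

Closed forms (geometric series, q = 1 - psi_bar):

    P(detect)        = 1 - (1-phi) q / (1 - phi q) - psi (1-phi) / (1 - phi q)**2
    P(span = d, det) = psi**2 (1-phi) phi**(d-1) / (1 - phi q)**2        (d >= 2)
    P(unobserved)    = 1 - P(detect)

The conditional span pmf P(span = d | detected) sums to one exactly.  phi is
fit by maximizing the conditional log-likelihood over logit(phi) with a
bounded 1-D search; the asymptotic variance is the inverse negative second
derivative of the log-likelihood at the optimum (numerical differentiation),
and the tract-length interval is the endpoint transformation
1 / (1 - (phi_hat +/- 1.96 SE)) clipped to (0, inf).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .io import ConversionTract, PhiFit, RegionMap

_EPS = 1e-12


def tract_length_pmf(phi: float, length) -> np.ndarray | float:
    """P(L = length) for the geometric tract-length model."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    length = np.asarray(length)
    if (length < 1).any():
        raise ValueError("tract lengths start at 1")
    out = (1.0 - phi) * phi ** (length - 1)
    return out if out.shape else float(out)


def mean_tract_length(phi: float) -> float:
    """Geometric mean tract length 1 / (1 - phi)."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    return 1.0 / (1.0 - phi)


def detection_probability(phi: float, psi_bar: float) -> float:
    """P(a true tract shows >= 2 informative sites | phi, psi_bar)."""
    _check_params(phi, psi_bar)
    q = 1.0 - psi_bar
    denom = 1.0 - phi * q
    return 1.0 - (1.0 - phi) * q / denom - psi_bar * (1.0 - phi) / denom**2


def p_unobserved(phi: float, psi_bar: float) -> float:
    """P(a true tract yields < 2 informative sites and is never seen)."""
    return 1.0 - detection_probability(phi, psi_bar)


def observed_span_likelihood(d, phi: float, psi_bar: float):
    """P(observed span = d | tract detected); vectorized over d (d >= 2)."""
    _check_params(phi, psi_bar)
    d = np.asarray(d)
    if (d < 2).any():
        raise ValueError("observed spans require >= 2 informative sites (d >= 2)")
    q = 1.0 - psi_bar
    denom = 1.0 - phi * q
    p_det = detection_probability(phi, psi_bar)
    if p_det <= _EPS:
        raise ValueError("degenerate (phi, psi_bar): detection probability ~ 0")
    out = psi_bar**2 * (1.0 - phi) * phi ** (d - 1) / (denom**2 * p_det)
    return out if out.shape else float(out)


def _check_params(phi: float, psi_bar: float) -> None:
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    if not 0.0 < psi_bar <= 1.0:
        raise ValueError("psi_bar must lie in (0, 1]")


def _neg_loglik(logit_phi: float, span_values: np.ndarray,
                span_counts: np.ndarray, psi_bar: float) -> float:
    phi = 1.0 / (1.0 + np.exp(-logit_phi))
    phi = min(max(phi, _EPS), 1.0 - _EPS)
    q = 1.0 - psi_bar
    denom = 1.0 - phi * q
    p_det = detection_probability(phi, psi_bar)
    if p_det <= _EPS:
        return np.inf
    n = span_counts.sum()
    ll = (
        n * (2.0 * np.log(psi_bar) + np.log1p(-phi)
             - 2.0 * np.log(denom) - np.log(p_det))
        + np.log(phi) * float(((span_values - 1) * span_counts).sum())
    )
    return -ll


def fit_phi(
    observed_spans: Sequence[int],
    psi_per_tract: Sequence[float] | float,
    region_id: str = "",
    donor: str = "",
    recipient: str = "",
    tol: float = 1e-8,
) -> PhiFit:
    """Maximum-likelihood phi for one (region, donor, recipient) group.

    ``observed_spans`` are the outermost-informative-site spans (bp, >= 2);
    ``psi_per_tract`` is each tract's mean psi (pooled here by arithmetic
    mean) or a single pooled value.  Requires at least two tracts.
    """
    spans = np.asarray(observed_spans, dtype=np.int64)
    if len(spans) < 2:
        raise ValueError("insufficient data: need >= 2 observed tracts")
    if (spans < 2).any():
        raise ValueError("observed spans must be >= 2")
    psi_bar = float(np.mean(psi_per_tract))
    _check_params(0.5, psi_bar)

    values, cnt = np.unique(spans, return_counts=True)
    res = minimize_scalar(
        _neg_loglik, bounds=(-30.0, 30.0), method="bounded",
        args=(values, cnt, psi_bar), options={"xatol": tol},
    )
    phi_hat = float(1.0 / (1.0 + np.exp(-res.x)))
    phi_hat = min(max(phi_hat, _EPS), 1.0 - _EPS)
    if res.x <= -29.9 or res.x >= 29.9 or (values == values.min()).all():
        warnings.warn("phi estimate at or near a boundary; spans carry little "
                      "length information", RuntimeWarning, stacklevel=2)

    # numerical second derivative of the log-likelihood on the phi scale
    h = max(1e-6, (1.0 - phi_hat) * 1e-3)
    h = min(h, phi_hat / 2, (1.0 - phi_hat) / 2)

    def nll_phi(p: float) -> float:
        x = np.log(p) - np.log1p(-p)
        return _neg_loglik(x, values, cnt, psi_bar)

    d2 = (nll_phi(phi_hat + h) - 2.0 * nll_phi(phi_hat)
          + nll_phi(phi_hat - h)) / h**2
    variance = 1.0 / d2 if d2 > 0 else np.inf
    se = np.sqrt(variance) if np.isfinite(variance) else np.inf

    phi_lo = max(phi_hat - 1.96 * se, _EPS)
    phi_hi = min(phi_hat + 1.96 * se, 1.0 - _EPS)
    p_un = p_unobserved(phi_hat, psi_bar)
    k = len(spans)
    return PhiFit(
        region_id=region_id, donor=donor, recipient=recipient,
        phi_hat=phi_hat,
        asymptotic_variance=float(variance),
        tract_length_mean=mean_tract_length(phi_hat),
        tract_length_low=mean_tract_length(phi_lo),
        tract_length_high=mean_tract_length(phi_hi),
        p_unobserved=p_un,
        expected_k=k / (1.0 - p_un),
        n_observed=k,
    )


def expected_tract_number(observed_k: int, phi_hat: float,
                          psi_bar: float) -> tuple[float, float]:
    """(p_unobserved, expected true tract number) given the fitted model.

    expected_k = observed_k / (1 - p_unobserved) and is always >= observed_k.
    """
    if observed_k == 0:
        return (p_unobserved(phi_hat, psi_bar) if psi_bar > 0 else 1.0, 0.0)
    if psi_bar <= 0.0:
        raise ValueError("undetectable regime: psi_bar = 0 implies "
                         "p_unobserved = 1")
    p_un = p_unobserved(phi_hat, psi_bar)
    if p_un >= 1.0 - _EPS:
        raise ValueError("undetectable regime: p_unobserved ~ 1")
    return p_un, observed_k / (1.0 - p_un)


def fit_phi_by_group(
    tracts: Iterable[ConversionTract],
    region_map: RegionMap,
    min_tracts: int = 2,
) -> list[PhiFit]:
    """One PhiFit per (region, donor, recipient).

    A tract detected under several donors enters each of those donor groups,
    mirroring the per-pair detection lists the fits are estimated from.
    Groups with fewer than ``min_tracts`` tracts are skipped with a warning.
    """
    groups: dict[tuple[str, str, str], list[ConversionTract]] = {}
    for t in tracts:
        ridx = int(region_map.region_index_of(np.asarray([t.start]))[0])
        if ridx < 0:
            continue
        rid = region_map.regions[ridx][0]
        for donor in t.donor_arrangements:
            groups.setdefault((rid, donor, t.recipient_arrangement), []).append(t)

    fits = []
    for (rid, donor, recip), group in sorted(groups.items()):
        if len(group) < min_tracts:
            warnings.warn(f"region {rid} {donor}->{recip}: only {len(group)} "
                          "tracts; skipped", RuntimeWarning, stacklevel=2)
            continue
        spans = [t.span for t in group]
        psis = [t.mean_psi for t in group]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fits.append(fit_phi(spans, psis, region_id=rid, donor=donor,
                                recipient=recip))
    return fits


__all__ = [
    "tract_length_pmf", "mean_tract_length", "detection_probability",
    "p_unobserved", "observed_span_likelihood", "fit_phi",
    "expected_tract_number", "fit_phi_by_group",
]
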