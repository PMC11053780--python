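"""Algebra of the ¹⁴N nuclear-quadrupole-resonance frequency triplet.

A spin-1 nucleus in zero field shows up to three resonance lines
ν₊ ≥ ν₋ ≥ ν₀ with ν₀ = ν₊ − ν₋.  The pair (ν₊, ν₋) determines the
quadrupole coupling constant and the EFG asymmetry parameter:

    e²qQ/h = (2/3)(ν₊ + ν₋)          η = 3(ν₊ − ν₋)/(ν₊ + ν₋)

and conversely ν± = (e²qQ/h)/4 · (3 ± η), ν₀ = (e²qQ/h)/2 · η.
Experiment yields only the magnitude of e²qQ/h; calculated values may be
signed and are carried in a separate optional field.

The module also provides a triplet validator (printed tables occasionally
disagree with the algebra; the validator reports, never corrects) and an
experiment-versus-calculation agreement summary based on ordinary least
squares.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from pydantic import BaseModel, model_validator
from scipy import stats

from .errors import DomainError, InvalidTripletError, SchemaError

__all__ = [
    "NQRTriplet",
    "QuadrupoleParams",
    "TripletValidation",
    "AgreementSummary",
    "quadrupole_from_frequencies",
    "frequencies_from_quadrupole",
    "validate_triplet",
    "spectrum_agreement",
]


class NQRTriplet(BaseModel):
    """Observed frequency triplet of one nitrogen site, in MHz.

    ``nu_zero`` may be absent (often not observed directly; derivable as
    ν₊ − ν₋).  Consistency of a present ``nu_zero`` is *not* enforced here —
    printed tables carry rounded and occasionally inconsistent values — use
    :func:`validate_triplet` to audit it.
    """

    nu_plus: float
    nu_minus: float
    nu_zero: Optional[float] = None
    site_label: str = ""
    assignment: Optional[str] = None

    @model_validator(mode="after")
    def _check_order(self) -> "NQRTriplet":
        if self.nu_minus < 0 or self.nu_plus < self.nu_minus:
            raise ValueError(
                f"require nu_plus >= nu_minus >= 0, got "
                f"({self.nu_plus}, {self.nu_minus})"
            )
        return self


class QuadrupoleParams(BaseModel):
    """|e²qQ/h| (MHz) and asymmetry parameter η ∈ [0, 1].

    ``cqcc`` stores the magnitude; ``cqcc_signed`` optionally carries the
    signed value from an electronic-structure calculation.
    """

    cqcc: float
    eta: float
    cqcc_signed: Optional[float] = None
    site_label: str = ""

    @model_validator(mode="after")
    def _check_range(self) -> "QuadrupoleParams":
        if self.cqcc < 0:
            raise ValueError(f"cqcc must be >= 0, got {self.cqcc}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")
        return self


class TripletValidation(BaseModel):
    """Audit report for one triplet; flags, never corrections."""

    nu_zero_consistent: Optional[bool] = None  # None when nu_zero absent
    implied_eta: float
    eta_in_range: bool
    params_match_printed: Optional[bool] = None
    flags: list[str] = []

    @property
    def ok(self) -> bool:
        return (
            self.nu_zero_consistent is not False
            and self.eta_in_range
            and self.params_match_printed is not False
        )


class AgreementSummary(BaseModel):
    """OLS summary of experimental frequencies against calculated ones."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int

    @model_validator(mode="after")
    def _check(self) -> "AgreementSummary":
        if self.n_points < 2:
            raise ValueError("need at least 2 paired frequencies")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        return self


def quadrupole_from_frequencies(
    nu_plus: float, nu_minus: float, site_label: str = ""
) -> QuadrupoleParams:
    """Invert the frequency pair to (|e²qQ/h|, η).

    Requires ν₊ ≥ ν₋ > 0 and ν₋ ≥ ν₊/2; the latter is exactly the η ≤ 1
    condition and its violation raises :class:`InvalidTripletError`.
    """
    if nu_plus <= 0 or nu_minus <= 0:
        raise DomainError(f"frequencies must be positive, got ({nu_plus}, {nu_minus})")
    if nu_minus > nu_plus:
        raise DomainError(f"require nu_plus >= nu_minus, got ({nu_plus}, {nu_minus})")
    if nu_minus < nu_plus / 2:
        raise InvalidTripletError(
            f"nu_minus < nu_plus/2 implies eta > 1 for ({nu_plus}, {nu_minus})"
        )
    cqcc = (2.0 / 3.0) * (nu_plus + nu_minus)
    eta = 3.0 * (nu_plus - nu_minus) / (nu_plus + nu_minus)
    return QuadrupoleParams(cqcc=cqcc, eta=min(eta, 1.0), site_label=site_label)


def frequencies_from_quadrupole(params: QuadrupoleParams) -> NQRTriplet:
    """Forward map (|e²qQ/h|, η) → (ν₊, ν₋, ν₀)."""
    nu_plus = params.cqcc / 4.0 * (3.0 + params.eta)
    nu_minus = params.cqcc / 4.0 * (3.0 - params.eta)
    return NQRTriplet(
        nu_plus=nu_plus,
        nu_minus=nu_minus,
        nu_zero=nu_plus - nu_minus,
        site_label=params.site_label,
    )


def validate_triplet(
    t: NQRTriplet,
    tol: float = 0.005,
    printed: QuadrupoleParams | None = None,
    decimals: int = 3,
) -> TripletValidation:
    """Audit a triplet: ν₀ consistency at ``tol`` MHz, implied η range and,
    optionally, agreement of the recomputed parameters with printed ones at
    ``decimals`` decimal places (the printed-table convention)."""
    flags: list[str] = []
    total = t.nu_plus + t.nu_minus
    implied_eta = 3.0 * (t.nu_plus - t.nu_minus) / total if total > 0 else math.inf
    eta_ok = 0.0 <= implied_eta <= 1.0
    if not eta_ok:
        flags.append(f"implied eta {implied_eta:.3f} outside [0, 1]")

    nu_zero_consistent: Optional[bool] = None
    if t.nu_zero is not None:
        nu_zero_consistent = abs(t.nu_zero - (t.nu_plus - t.nu_minus)) <= tol
        if not nu_zero_consistent:
            flags.append(
                f"nu_zero {t.nu_zero} differs from nu_plus - nu_minus = "
                f"{t.nu_plus - t.nu_minus:.3f} by more than {tol} MHz"
            )

    params_match: Optional[bool] = None
    if printed is not None:
        cqcc = (2.0 / 3.0) * total
        match_c = round(cqcc, decimals) == round(printed.cqcc, decimals)
        match_e = eta_ok and round(implied_eta, decimals) == round(printed.eta, decimals)
        params_match = match_c and match_e
        if not match_c:
            flags.append(
                f"recomputed cqcc {cqcc:.{decimals}f} != printed {printed.cqcc}"
            )
        if not match_e:
            flags.append(
                f"recomputed eta {implied_eta:.{decimals}f} != printed {printed.eta}"
            )

    return TripletValidation(
        nu_zero_consistent=nu_zero_consistent,
        implied_eta=implied_eta,
        eta_in_range=eta_ok,
        params_match_printed=params_match,
        flags=flags,
    )


def spectrum_agreement(
    experimental: Sequence[float], calculated: Sequence[float]
) -> AgreementSummary:
    """OLS regression of experimental frequencies on calculated ones.

    Lists are paired by site and must have equal length ≥ 2.  The residual
    standard deviation uses n − 2 degrees of freedom (0 for the exact
    two-point fit).
    """
    if len(experimental) != len(calculated):
        raise SchemaError(
            f"paired lists differ in length: {len(experimental)} vs {len(calculated)}"
        )
    n = len(experimental)
    if n < 2:
        raise DomainError("need at least 2 paired frequencies")
    res = stats.linregress(calculated, experimental)
    fitted = [res.slope * c + res.intercept for c in calculated]
    ssr = sum((e - f) ** 2 for e, f in zip(experimental, fitted))
    residual_sd = math.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    r_squared = res.rvalue**2
    if n == 2:  # two points define the line exactly
        r_squared = 1.0
    return AgreementSummary(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=min(r_squared, 1.0),
        residual_sd=residual_sd,
        n_points=n,
    )
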