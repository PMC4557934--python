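"""Per-individual fish biology: growth, mortality, survivorship and weight.

The production model works at the level of a single fish of observed total
length ``L`` (cm).  Its annual somatic production is the survivorship-
discounted one-year growth in weight,

    P(L) = S(M(L)) * (W(L + dL(L)) - W(L)),

where ``dL`` is the Fabens form of the von Bertalanffy growth increment,
``M`` is a length-based instantaneous natural mortality rate, ``S`` the
annual survivorship and ``W`` a power-law weight-at-length relation.
Production is defined to be zero at and beyond the asymptotic length
``L_inf``: fish at the asymptote no longer grow in the model.

All lengths are total length in cm, weights in grams, rates per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GISLASON_COEFFS",
    "TaxonParameters",
    "fabens_increment",
    "natural_mortality",
    "survivorship",
    "weight_at_length",
    "individual_production",
    "recruit_length_threshold",
    "resolve_taxon",
]

#: Coefficients (c0, c_L, c_Linf) of the length-based natural mortality
#: estimator ln M = c0 + c_L*ln L + c_Linf*ln L_inf + ln K.  Empirical
#: constants from the literature; overridable per call for sensitivity runs.
GISLASON_COEFFS: tuple[float, float, float] = (0.55, -1.61, 1.44)


@dataclass(frozen=True)
class TaxonParameters:
    """Life-history constants for one taxon.

    Parameters
    ----------
    taxon_code
        Label used in survey records (species or group code).
    L_inf
        Asymptotic total length of the von Bertalanffy growth curve, cm.
    K
        von Bertalanffy growth coefficient, 1/yr.
    weight_a, weight_b
        Coefficients of the weight-at-length power law ``W = a * L**b``
        with ``W`` in grams and ``L`` in cm.
    length_conversion
        Optional ``(slope, intercept)`` affine map applied to the measured
        length before the weight relation, for taxa whose published
        relations use a different length type (e.g. fork vs total length).
    transient
        Transient, highly mobile taxa are excluded from surveys.
    proxy_for
        Survey codes (e.g. an unidentified-rockfish group) that this
        taxon's parameters stand in for.
    """

    taxon_code: str
    L_inf: float
    K: float
    weight_a: float
    weight_b: float
    length_conversion: tuple[float, float] | None = None
    transient: bool = False
    proxy_for: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("L_inf", "K", "weight_a", "weight_b"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.taxon_code}: {name} must be finite and > 0, got {v}")


def _check_finite(L: float) -> None:
    if not math.isfinite(L):
        raise ValueError(f"length must be finite, got {L}")


def fabens_increment(L: float, params: TaxonParameters, dt: float = 1.0) -> float:
    """One-interval length increment from the Fabens growth form.

    ``dL = (L_inf - L) * (1 - exp(-K*dt))``, clamped at zero so that fish
    observed at or beyond ``L_inf`` (possible with 5-cm binned lengths) do
    not shrink.
    """
    _check_finite(L)
    if L < 0:
        raise ValueError(f"length must be >= 0, got {L}")
    return max(0.0, (params.L_inf - L) * (1.0 - math.exp(-params.K * dt)))


def natural_mortality(
    L: float,
    params: TaxonParameters,
    coeffs: tuple[float, float, float] = GISLASON_COEFFS,
) -> float:
    """Length-based instantaneous natural mortality rate M (1/yr).

    ``M = exp(c0) * L**c_L * L_inf**c_Linf * K`` — strictly decreasing in
    L for the default coefficients, so small fish die at much higher rates.
    """
    _check_finite(L)
    if L <= 0:
        raise ValueError(f"mortality is undefined for L <= 0, got {L}")
    c0, cL, cLinf = coeffs
    log_M = c0 + cL * math.log(L) + cLinf * math.log(params.L_inf) + math.log(params.K)
    # for vanishingly small L the rate is astronomically large; report it
    # as infinite rather than overflowing (survivorship is then exactly 0)
    if log_M > 700.0:
        return math.inf
    return math.exp(log_M)


def survivorship(M: float, dt: float = 1.0) -> float:
    """Fraction surviving an interval of dt years under constant rate M.

    An infinite rate is a valid limit (nobody survives).
    """
    if math.isnan(M) or M < 0:
        raise ValueError(f"mortality rate must be >= 0, got {M}")
    return math.exp(-M * dt)


def weight_at_length(L: float, params: TaxonParameters) -> float:
    """Weight in grams from the power law, after any length conversion."""
    _check_finite(L)
    if L < 0:
        raise ValueError(f"length must be >= 0, got {L}")
    if params.length_conversion is not None:
        slope, intercept = params.length_conversion
        L = slope * L + intercept
        if L < 0:
            L = 0.0
    return params.weight_a * L**params.weight_b


def individual_production(L: float, params: TaxonParameters, dt: float = 1.0) -> float:
    """Expected annual somatic production of one fish of length L, g/yr.

    The survivorship-discounted growth in weight over one interval.  Zero
    for ``L >= L_inf``; mortality is evaluated at the start-of-interval
    length.  Never negative.
    """
    _check_finite(L)
    if L < 0:
        raise ValueError(f"length must be >= 0, got {L}")
    if L >= params.L_inf:
        return 0.0
    if L == 0:
        # A zero-length fish carries no survivable biomass; treat as no
        # production rather than evaluating M at L=0.
        return 0.0
    S = survivorship(natural_mortality(L, params), dt)
    dW = weight_at_length(L + fabens_increment(L, params, dt), params) - weight_at_length(L, params)
    return max(0.0, S * dW)


def recruit_length_threshold(
    params: TaxonParameters, settlement_length: float = 1.0, dt: float = 1.0
) -> float:
    """Length a recruit reaches after one interval of growth from settlement.

    Individuals observed at or below this length settled within the last
    interval; their standing biomass counts as recruitment production.
    """
    if settlement_length < 0:
        raise ValueError("settlement length must be >= 0")
    return settlement_length + fabens_increment(settlement_length, params, dt)


def resolve_taxon(
    taxon_code: str,
    params_table: dict[str, TaxonParameters],
    proxy_map: dict[str, str] | None = None,
) -> TaxonParameters:
    """Look up the parameters for a survey code, following proxy rules.

    ``proxy_map`` maps unidentified survey codes to the donor taxon whose
    parameters stand in for them (e.g. unidentified rockfish -> Squarespot
    Rockfish).  Codes declared in a donor's ``proxy_for`` list resolve the
    same way.  Unknown codes raise ``KeyError`` naming the code.
    """
    if taxon_code in params_table:
        return params_table[taxon_code]
    if proxy_map and taxon_code in proxy_map:
        donor = proxy_map[taxon_code]
        if donor not in params_table:
            raise KeyError(f"proxy donor {donor!r} for {taxon_code!r} not in parameter table")
        return params_table[donor]
    for params in params_table.values():
        if taxon_code in params.proxy_for:
            return params
    raise KeyError(f"taxon {taxon_code!r} not in parameter table and no proxy rule applies")
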