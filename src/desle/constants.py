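"""Physical constants and conventional melting-entropy values (SI units)."""

#: Universal gas constant, J/(mol K) (CODATA 2018).
R = 8.314462618

#: Walden-rule melting entropy for rigid molecules in ordered crystals,
#: J/(mol K) (dSm/R ~ 7).
WALDEN_ENTROPY = 54.4

#: Conventional low melting entropy for rigid molecules in disordered
#: crystals, J/(mol K) (dSm/R ~ 2.4).
LOW_ENTROPY = 20.0

#: Named entropy conventions accepted wherever an entropy value is expected.
ENTROPY_CONVENTIONS = {"walden": WALDEN_ENTROPY, "low": LOW_ENTROPY}


def resolve_entropy(value: float | str) -> float:
    """Map an entropy convention name ('walden' / 'low') or a numeric value
    in J/(mol K) to a float."""
    if isinstance(value, str):
        try:
            return ENTROPY_CONVENTIONS[value.lower()]
        except KeyError:
            raise ValueError(
                f"unknown entropy convention {value!r}; "
                f"expected one of {sorted(ENTROPY_CONVENTIONS)} or a number"
            ) from None
    v = float(value)
    if v < 0:
        raise ValueError("melting entropy must be non-negative")
    return v
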