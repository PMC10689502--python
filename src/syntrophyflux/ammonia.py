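"""Free-ammonia speciation in anaerobic digester liquor.

Total ammonium nitrogen (TAN = NH4+ + NH3, as N) partitions between the
ionized and unionized forms according to pH and temperature.  The unionized
fraction is the microbially inhibitory species, so thermophilic, high-ammonia
digesters are routinely characterized by their free NH3-N concentration.

The default acid-dissociation constant follows the Emerson-type van't Hoff
relation

    pKa(T) = 0.09018 + 2729.92 / T      (T in kelvin)

which reproduces tabulated NH4+/NH3 equilibria over 0-60 degC to within the
precision relevant for digester work.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AmmoniaConditions", "ammonia_pka", "free_ammonia_fraction", "free_ammonia"]


@dataclass(frozen=True)
class AmmoniaConditions:
    """Reactor chemistry scalars controlling NH3 speciation.

    tan : total ammonium nitrogen, g N/L (NH4+ plus NH3, both as N)
    ph : pH units
    temperature : kelvin
    """

    tan: float
    ph: float
    temperature: float = 328.15

    def __post_init__(self) -> None:
        if self.tan < 0:
            raise ValueError(f"TAN must be >= 0, got {self.tan}")
        if not 0 < self.ph < 14:
            raise ValueError(f"pH must be in (0, 14), got {self.ph}")
        if self.temperature <= 273:
            raise ValueError(
                f"temperature must be > 273 K (liquid water), got {self.temperature}"
            )


def ammonia_pka(temperature: float) -> float:
    """Temperature-dependent pKa of the NH4+/NH3 couple (Emerson relation)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive kelvin")
    return 0.09018 + 2729.92 / temperature


def free_ammonia_fraction(ph: float, temperature: float) -> float:
    """Unionized fraction NH3 / (NH3 + NH4+) at the given pH and temperature.

    Strictly between 0 and 1 for finite pH; equals 1/2 when pH = pKa(T).
    """
    pka = ammonia_pka(temperature)
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def free_ammonia(cond: AmmoniaConditions) -> float:
    """Free ammonia concentration, g NH3-N/L.

    >>> round(free_ammonia(AmmoniaConditions(tan=1.6, ph=8.0, temperature=328.15)), 2)
    0.45
    """
    return cond.tan * free_ammonia_fraction(cond.ph, cond.temperature)
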