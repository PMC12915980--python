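"""Unit constants used throughout the package.

Maritime sources mix metric tonnes with U.S. customary ("long") tons, so the
conversion constants are centralised here and treated as read-only.
"""

from types import MappingProxyType

TONNE_KG: float = 1000.0
#: U.S. customary ton (long ton) in kg; some published DWT equations emit this unit.
US_TON_KG: float = 1016.0
#: Mass budget for one person when correcting a light-ship (net) weight.
PERSON_KG: float = 75.0
#: Mass budget for one piece of luggage per person.
LUGGAGE_KG: float = 20.0
#: One knot in km/h.
KNOT_KMH: float = 1.852
#: One knot in m/s (1.852 km/h / 3.6).
KNOT_MS: float = KNOT_KMH / 3.6

UNIT_CONSTANTS = MappingProxyType(
    {
        "tonne_kg": TONNE_KG,
        "us_ton_kg": US_TON_KG,
        "person_kg": PERSON_KG,
        "luggage_kg": LUGGAGE_KG,
        "knot_kmh": KNOT_KMH,
        "knot_ms": KNOT_MS,
    }
)
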