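"""The fixed catalogue of neurodevelopmental test domains.

Twenty domains drawn from four instruments define the substrate of the
multimorbidity analysis:

* Touwen neurological examination — eight functional domains whose
  dysfunction count yields a single derived domain, minor neurological
  dysfunction (``MND``);
* MABC-2 (Movement Assessment Battery for Children, 2nd ed.) — three
  subtests on a standard-score scale (mean 10, SD 3, integers 1–19);
* SIPT (Sensory Integration and Praxis Test) — six tests reported as
  z-scores in [−3, +3];
* NEPSY-II (Developmental Neuropsychological Assessment, 2nd ed.) — ten
  subtests on a scaled-score scale (mean 10, SD 3, integers 1–19).

"Impaired" means performance more than one SD below test norms on the
instrument's native scale: standard/scaled score ≤ 7 for MABC-2 and
NEPSY-II, z < −1.0 for SIPT (strict by default, see
:func:`comorbmap.classify.is_impaired`), and simple-or-complex MND for the
Touwen examination.

The registry also fixes the circular layout used by the relationship maps:
motor/sensorimotor instruments run clockwise along the upper semicircle,
neuropsychological subtests anti-clockwise along the lower one, so both
sequences read left to right.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class Instrument(str, enum.Enum):
    TOUWEN = "TOUWEN"
    MABC2 = "MABC2"
    SIPT = "SIPT"
    NEPSY2 = "NEPSY2"


class Scale(str, enum.Enum):
    """Native score scale of an instrument."""

    #: count of dysfunctional Touwen domains (0–8), categorised as MND
    BINARY_DYSFUNCTION_COUNT = "binary-dysfunction-count"
    #: MABC-2 standard score: integer 1–19, mean 10, SD 3
    STANDARD_SCORE = "standard-score"
    #: SIPT z-score: continuous, clipped to [−3, +3]
    Z_SCORE = "z-score"
    #: NEPSY-II scaled score: integer 1–19, mean 10, SD 3
    SCALED_SCORE = "scaled-score"


@dataclass(frozen=True)
class DomainSpec:
    """One test domain: identity, native scale, and impairment threshold."""

    abbreviation: str
    name: str
    instrument: Instrument
    scale: Scale

    @property
    def native_mean(self) -> float:
        return 0.0 if self.scale is Scale.Z_SCORE else 10.0

    @property
    def native_sd(self) -> float:
        return 1.0 if self.scale is Scale.Z_SCORE else 3.0

    @property
    def valid_range(self) -> tuple[float, float]:
        if self.scale is Scale.Z_SCORE:
            return (-3.0, 3.0)
        if self.scale is Scale.BINARY_DYSFUNCTION_COUNT:
            return (0.0, 8.0)
        return (1.0, 19.0)

    @property
    def is_integer_scale(self) -> bool:
        return self.scale in (Scale.STANDARD_SCORE, Scale.SCALED_SCORE)

    def cutoff_z(self) -> float:
        """Impairment threshold expressed on the latent z scale.

        For the integer scales a raw draw rounds to ≤ 7 exactly when the
        continuous value falls below 7.5, i.e. z < −5/6; SIPT impairment is
        z < −1.  The Touwen-derived MND domain has no score cutoff.
        """
        if self.scale is Scale.Z_SCORE:
            return -1.0
        if self.is_integer_scale:
            return (7.0 + 0.5 - self.native_mean) / self.native_sd
        raise ValueError(f"{self.abbreviation} has no score cutoff")


#: Touwen functional domains, in examination order.
TOUWEN_DOMAINS: tuple[str, ...] = (
    "posture_muscle_tone",
    "reflexes",
    "involuntary_movements",
    "coordination_balance",
    "fine_manipulation",
    "associated_movements",
    "sensory_function",
    "cranial_nerve_function",
)

_UPPER = (
    DomainSpec("MND", "minor neurological dysfunction", Instrument.TOUWEN,
               Scale.BINARY_DYSFUNCTION_COUNT),
    DomainSpec("MD", "manual dexterity", Instrument.MABC2, Scale.STANDARD_SCORE),
    DomainSpec("AC", "aiming and catching", Instrument.MABC2, Scale.STANDARD_SCORE),
    DomainSpec("BAL", "balance", Instrument.MABC2, Scale.STANDARD_SCORE),
    DomainSpec("MFP", "manual form perception", Instrument.SIPT, Scale.Z_SCORE),
    DomainSpec("FI", "finger identification", Instrument.SIPT, Scale.Z_SCORE),
    DomainSpec("DC", "design copying", Instrument.SIPT, Scale.Z_SCORE),
    DomainSpec("MAc", "motor accuracy", Instrument.SIPT, Scale.Z_SCORE),
    DomainSpec("PPr", "postural praxis", Instrument.SIPT, Scale.Z_SCORE),
    DomainSpec("BMC", "bilateral motor coordination", Instrument.SIPT, Scale.Z_SCORE),
)

_LOWER = (
    DomainSpec("AuAttn", "auditory attention", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("VisAttn", "visual attention", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("MemoD", "memory for designs", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("MemoF", "memory for faces", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("MemoN", "narrative memory", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("ImHP", "imitating hand positions", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("Arrows", "arrows", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("BloC", "block construction", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("DeCo", "design copying", Instrument.NEPSY2, Scale.SCALED_SCORE),
    DomainSpec("GeoP", "geometric puzzles", Instrument.NEPSY2, Scale.SCALED_SCORE),
)


class DomainRegistry:
    """Ordered, immutable collection of the 20 test domains.

    ``layout_order`` is identical to iteration order: the upper-semicircle
    domains (Touwen/MABC-2/SIPT) followed by the lower-semicircle NEPSY-II
    domains.
    """

    def __init__(self, entries: tuple[DomainSpec, ...] = _UPPER + _LOWER):
        abbrs = [e.abbreviation for e in entries]
        if len(set(abbrs)) != len(abbrs):
            raise ValueError("domain abbreviations must be unique")
        self._entries = tuple(entries)
        self._by_abbr = {e.abbreviation: e for e in entries}
        if entries == _UPPER + _LOWER:
            counts = {
                Instrument.TOUWEN: 1, Instrument.MABC2: 3,
                Instrument.SIPT: 6, Instrument.NEPSY2: 10,
            }
            for instr, n in counts.items():
                assert sum(e.instrument is instr for e in entries) == n

    @property
    def entries(self) -> tuple[DomainSpec, ...]:
        return self._entries

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self._entries)

    @property
    def layout_order(self) -> tuple[str, ...]:
        return self.abbreviations

    @property
    def score_domains(self) -> tuple[DomainSpec, ...]:
        """The 19 domains carrying raw scores (everything but MND)."""
        return tuple(e for e in self._entries if e.abbreviation != "MND")

    def upper_semicircle(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self._entries[:10])

    def lower_semicircle(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self._entries[10:])

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._by_abbr

    def __getitem__(self, abbreviation: str) -> DomainSpec:
        try:
            return self._by_abbr[abbreviation]
        except KeyError:
            raise KeyError(
                f"unknown domain {abbreviation!r}; valid codes: "
                + ", ".join(self.abbreviations)
            ) from None

    def index(self, abbreviation: str) -> int:
        return self.abbreviations.index(abbreviation)

    def layout_positions(self, radius: float = 1.0) -> dict[str, tuple[float, float]]:
        """Node coordinates for the relationship-map figure.

        Upper-semicircle domains are placed clockwise from the upper left,
        lower-semicircle domains anti-clockwise from the lower left, so both
        read left to right.
        """
        pos: dict[str, tuple[float, float]] = {}
        upper, lower = self.upper_semicircle(), self.lower_semicircle()
        for i, abbr in enumerate(upper):
            theta = math.pi * (1 - (i + 0.5) / len(upper))
            pos[abbr] = (radius * math.cos(theta), radius * math.sin(theta))
        for i, abbr in enumerate(lower):
            theta = math.pi * (1 + (i + 0.5) / len(lower))
            pos[abbr] = (radius * math.cos(theta), radius * math.sin(theta))
        return pos


#: The canonical registry instance used throughout the package.
DEFAULT_REGISTRY = DomainRegistry()
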