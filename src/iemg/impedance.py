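"""Electrode impedance computation and summaries.

Implanted EMG systems are routinely checked by injecting a small sinusoidal
current between pairs of connectors (each electrode plus the common
reference) and measuring the resulting voltage amplitude.  Ohm's law then
gives an impedance magnitude for every connector pair.  Two kinds of values
result:

* **direct impedance** -- between an electrode and the reference; a proxy
  for the quality of the electrode-tissue contact (lower is better for
  recording), and
* **cross-channel impedance** -- between two electrodes; a proxy for
  electrical isolation (higher means less crosstalk between channels).

The ratio of cross-channel to direct impedance summarizes isolation in a
scale-free way.  Open circuits (no conductive path at the test current) are
first-class citizens here: they are represented by the :data:`OPEN`
sentinel, which sorts above every finite impedance, survives quantile
summaries, and serializes as the literal string ``"OPEN"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


# ---------------------------------------------------------------------------
# OPEN sentinel
# ---------------------------------------------------------------------------

class _Open:
    """Open-circuit sentinel: compares greater than every finite number.

    A dedicated singleton rather than IEEE infinity so that serialized
    output can carry the literal string ``"OPEN"`` and arithmetic misuse
    fails loudly instead of propagating ``inf`` silently.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "OPEN"

    def __eq__(self, other) -> bool:
        return other is self

    def __hash__(self) -> int:
        return hash("iemg.OPEN")

    def __lt__(self, other) -> bool:
        return False

    def __le__(self, other) -> bool:
        return other is self

    def __gt__(self, other) -> bool:
        return other is not self

    def __ge__(self, other) -> bool:
        return True


OPEN = _Open()
#: Union type for impedance-like values.
Ohm = "float | _Open"


def is_open(value) -> bool:
    """True if *value* is the OPEN sentinel."""
    return value is OPEN


def open_sort_key(value):
    """Sort key placing OPEN above all finite values (OPEN values tie)."""
    return (1, 0.0) if value is OPEN else (0, float(value))


def to_json_value(value):
    """Serialize a possibly-OPEN value: OPEN -> the string ``"OPEN"``."""
    return "OPEN" if value is OPEN else value


def from_json_value(value):
    """Inverse of :func:`to_json_value`."""
    return OPEN if value == "OPEN" else value


# ---------------------------------------------------------------------------
# Measurement and matrix types
# ---------------------------------------------------------------------------

REF = "REF"


@dataclass(frozen=True)
class ImpedanceMeasurement:
    """One voltage reading across a connector pair at one frequency.

    ``connector_a``/``connector_b`` are electrode ids or the string ``"REF"``
    for the common reference.  ``participant`` is an optional tag used to
    split multi-participant logs; it takes no part in the physics.
    """

    frequency_hz: float
    connector_a: str
    connector_b: str
    current_amp_A: float
    voltage_amp_V: float
    open_flag: bool = False
    participant: str | None = None

    def __post_init__(self):
        if self.current_amp_A <= 0:
            raise ValueError(f"current must be positive, got {self.current_amp_A}")
        if self.voltage_amp_V < 0:
            raise ValueError(f"voltage amplitude must be >= 0, got {self.voltage_amp_V}")
        if self.connector_a == self.connector_b:
            raise ValueError(f"connector pair must be distinct, got {self.connector_a!r} twice")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) connector pair."""
        return tuple(sorted((self.connector_a, self.connector_b)))


@dataclass
class ImpedanceMatrix:
    """Direct and cross-channel impedances at one frequency.

    ``direct_ohm`` maps electrode id -> ohms or OPEN; ``cross_ohm`` maps the
    canonical sorted electrode pair -> ohms or OPEN.  Missing entries are
    simply absent from the dicts (distinct from OPEN, which is a measured
    open circuit).
    """

    frequency_hz: float
    direct_ohm: dict = field(default_factory=dict)
    cross_ohm: dict = field(default_factory=dict)

    @property
    def electrodes(self) -> list[str]:
        ids = set(self.direct_ohm)
        for a, b in self.cross_ohm:
            ids.update((a, b))
        return sorted(ids)

    def missing_pairs(self, electrodes: Sequence[str] | None = None) -> list[tuple[str, str]]:
        """Electrode pairs (and REF pairs) with no measurement at all."""
        ids = sorted(electrodes) if electrodes is not None else self.electrodes
        absent: list[tuple[str, str]] = []
        for e in ids:
            if e not in self.direct_ohm:
                absent.append(tuple(sorted((e, REF))))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if (a, b) not in self.cross_ohm:
                    absent.append((a, b))
        return absent


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_impedance(voltage_amp_V: float, current_amp_A: float, open_flag: bool = False):
    """Impedance magnitude |Z| = V/I at the measurement frequency.

    An open-circuit flag short-circuits the division and returns OPEN.
    """
    if current_amp_A <= 0:
        raise ValueError(f"current must be positive, got {current_amp_A}")
    if open_flag:
        return OPEN
    return voltage_amp_V / current_amp_A


def build_impedance_matrix(measurements: Iterable[ImpedanceMeasurement],
                           frequency_hz: float) -> ImpedanceMatrix:
    """Assemble the direct/cross impedance matrix from pairwise measurements.

    Pairs containing the reference populate ``direct_ohm``; electrode pairs
    populate ``cross_ohm``.  A duplicated (frequency, pair) measurement is an
    error -- silently averaging could mask instrument faults.
    """
    matrix = ImpedanceMatrix(frequency_hz=frequency_hz)
    seen: set[tuple[str, str]] = set()
    for m in measurements:
        if m.frequency_hz != frequency_hz:
            continue
        pair = m.pair
        if pair in seen:
            raise ValueError(f"duplicate measurement for pair {pair} at {frequency_hz} Hz")
        seen.add(pair)
        z = compute_impedance(m.voltage_amp_V, m.current_amp_A, m.open_flag)
        if REF in pair:
            electrode = pair[0] if pair[1] == REF else pair[1]
            matrix.direct_ohm[electrode] = z
        else:
            matrix.cross_ohm[pair] = z
    return matrix


@dataclass
class RatioResult:
    """Ordered cross/direct impedance ratios.

    ``ratios`` maps the ordered pair (i, j) to cross{i,j}/direct{i}.  Both
    orderings of every unordered pair are emitted, because nothing singles
    out one of the two direct impedances as the natural denominator.
    ``anomalous`` lists ordered pairs where the direct impedance was OPEN
    while the cross-channel path was finite (physically suspect: no path to
    the reference but a path to a neighbour); their ratio is reported as 0.
    """

    frequency_hz: float
    ratios: dict = field(default_factory=dict)
    anomalous: list = field(default_factory=list)

    def values(self) -> list:
        return [self.ratios[k] for k in sorted(self.ratios)]


def impedance_ratio(matrix: ImpedanceMatrix) -> RatioResult:
    """Cross-channel / direct impedance ratio for every ordered electrode pair.

    High ratios mean the inter-electrode path is much more resistive than
    each electrode's path to ground, i.e. the channels are electrically
    independent.  OPEN cross-channel values yield OPEN ratios (perfect
    isolation at the test current).
    """
    result = RatioResult(frequency_hz=matrix.frequency_hz)
    for (a, b), cross in matrix.cross_ohm.items():
        for i, j in ((a, b), (b, a)):
            if i not in matrix.direct_ohm:
                raise KeyError(f"direct impedance for electrode {i!r} is absent")
            direct = matrix.direct_ohm[i]
            if cross is OPEN:
                result.ratios[(i, j)] = OPEN
            elif direct is OPEN:
                result.ratios[(i, j)] = 0.0
                result.anomalous.append((i, j))
            else:
                result.ratios[(i, j)] = cross / direct
    return result


def _quantile_open(sorted_values: Sequence, q: float):
    """Type-7 quantile over a sequence that may contain OPEN (pre-sorted).

    OPEN sorts above every finite value; any quantile landing on, or
    interpolating with positive weight toward, an OPEN order statistic is
    itself OPEN.
    """
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty input")
    h = (n - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    frac = h - lo
    a, b = sorted_values[lo], sorted_values[hi]
    if a is OPEN:
        return OPEN
    if b is OPEN:
        return OPEN if frac > 0 else a
    return a + frac * (b - a)


def summarize(values: Sequence):
    """(median, lower quartile, upper quartile) of possibly-OPEN values.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" convention) at probabilities 0.5, 0.25 and 0.75.
    """
    vals = list(values)
    if not vals:
        raise ValueError("empty input")
    vals.sort(key=open_sort_key)
    return (_quantile_open(vals, 0.5),
            _quantile_open(vals, 0.25),
            _quantile_open(vals, 0.75))
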