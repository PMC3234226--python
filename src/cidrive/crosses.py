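"""Domain types and I/O for tsetse mating-cross count data.

The experimental unit is a cage of mated females of one symbiont class
(female class) crossed to males of another, observed over two gonotrophic
cycles.  Each cage x cycle record is a binomial count: out of ``n_females``
mated females alive at the start of the cycle, ``n_deposits`` deposited a
larva.  Three fly lines occur:

* ``w`` -- wild type, carrying both *Wolbachia* and *Wigglesworthia*;
* ``a`` -- aposymbiotic (tetracycline-cleared), carrying neither;
* ``m`` -- ampicillin-treated, *Wigglesworthia*-free but *Wolbachia*-positive.

Only the five cross types run in the insectary experiment are admitted:
female x male = w*w, w*a, a*a, a*w and m*m.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "FlyClass",
    "CrossObservation",
    "CrossDataset",
    "CrossDataError",
    "SchemaError",
    "MODELED_CROSSES",
    "load_cross_table",
    "write_cross_table",
    "reconstruct_from_summary",
    "table1_fixture",
    "table2_eclosion",
    "CROSS_COLUMNS",
]


class CrossDataError(ValueError):
    """A record violates the cross-data invariants."""


class SchemaError(CrossDataError):
    """An input table is missing required columns."""


class FlyClass(enum.Enum):
    """Symbiont infection state of a fly line."""

    WILD_TYPE = "w"
    APOSYMBIOTIC = "a"
    WIGGLESWORTHIA_FREE = "m"

    @property
    def wolbachia(self) -> bool:
        """Whether the line carries *Wolbachia*."""
        return self is not FlyClass.APOSYMBIOTIC

    @property
    def wigglesworthia(self) -> bool:
        """Whether the line carries *Wigglesworthia*."""
        return self is FlyClass.WILD_TYPE

    @classmethod
    def from_label(cls, label: str) -> "FlyClass":
        try:
            return cls(label)
        except ValueError:
            raise CrossDataError(f"unknown fly class {label!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


W = FlyClass.WILD_TYPE
A = FlyClass.APOSYMBIOTIC
M = FlyClass.WIGGLESWORTHIA_FREE

#: The five cross types (female, male) present in the experiment.
MODELED_CROSSES: frozenset[tuple[FlyClass, FlyClass]] = frozenset(
    {(W, W), (W, A), (A, A), (A, W), (M, M)}
)

CROSS_COLUMNS = ["female_class", "male_class", "cycle", "cage_id", "n_females", "n_larvae"]


@dataclass(frozen=True)
class CrossObservation:
    """One cage x gonotrophic-cycle binomial record."""

    female: FlyClass
    male: FlyClass
    cycle: int
    cage_id: str
    n_females: int
    n_deposits: int

    def __post_init__(self) -> None:
        if self.cycle not in (1, 2):
            raise CrossDataError(f"cycle must be 1 or 2, got {self.cycle}")
        if self.n_females < 0:
            raise CrossDataError(f"n_females must be non-negative, got {self.n_females}")
        if not 0 <= self.n_deposits <= self.n_females:
            raise CrossDataError(
                f"deposits exceed females: n_deposits={self.n_deposits}, "
                f"n_females={self.n_females}"
            )

    @property
    def cross(self) -> tuple[FlyClass, FlyClass]:
        return (self.female, self.male)


@dataclass(frozen=True)
class CrossDataset:
    """An ordered, validated collection of cross observations."""

    observations: tuple[CrossObservation, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        seen: dict[tuple[FlyClass, FlyClass], int] = {}
        for i, obs in enumerate(self.observations):
            if obs.cross not in MODELED_CROSSES:
                raise CrossDataError(
                    f"observation {i}: cross {obs.female.value}x{obs.male.value} "
                    "is not one of the five modeled cross types"
                )
            seen[obs.cross] = max(seen.get(obs.cross, 0), obs.n_females)
        for cross, n_max in seen.items():
            if n_max == 0:
                raise CrossDataError(
                    f"cross {cross[0].value}x{cross[1].value} has no observation "
                    "with n_females > 0"
                )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[CrossObservation]:
        return iter(self.observations)

    def restrict(self, crosses: Iterable[tuple[FlyClass, FlyClass]]) -> "CrossDataset":
        """Subset to the given cross types (e.g. for single-cross checks)."""
        wanted = set(crosses)
        obs = tuple(o for o in self.observations if o.cross in wanted)
        return CrossDataset(obs, provenance=f"{self.provenance}|restricted")

    def pooled_counts(self) -> dict[tuple[FlyClass, FlyClass], tuple[int, int]]:
        """Total (deposits, females) per cross type, pooled over cages and cycles."""
        pooled: dict[tuple[FlyClass, FlyClass], tuple[int, int]] = {}
        for obs in self.observations:
            k, n = pooled.get(obs.cross, (0, 0))
            pooled[obs.cross] = (k + obs.n_deposits, n + obs.n_females)
        return pooled

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "female_class": [o.female.value for o in self.observations],
                "male_class": [o.male.value for o in self.observations],
                "cycle": [o.cycle for o in self.observations],
                "cage_id": [o.cage_id for o in self.observations],
                "n_females": [o.n_females for o in self.observations],
                "n_larvae": [o.n_deposits for o in self.observations],
            }
        )


def load_cross_table(path: str | Path) -> CrossDataset:
    """Read a cross-count CSV into a validated :class:`CrossDataset`.

    The file must have a header with columns ``female_class, male_class,
    cycle, cage_id, n_females, n_larvae``.  Row order is preserved.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"cage_id": str})
    missing = [c for c in CROSS_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    observations = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            observations.append(
                CrossObservation(
                    female=FlyClass.from_label(str(row.female_class)),
                    male=FlyClass.from_label(str(row.male_class)),
                    cycle=int(row.cycle),
                    cage_id=str(row.cage_id),
                    n_females=int(row.n_females),
                    n_deposits=int(row.n_larvae),
                )
            )
        except CrossDataError as exc:
            raise CrossDataError(f"row {i}: {exc}") from None
    return CrossDataset(tuple(observations), provenance=str(path))


def write_cross_table(dataset: CrossDataset, path: str | Path) -> None:
    """Write a dataset to the CSV schema read by :func:`load_cross_table`."""
    dataset.to_frame().to_csv(path, index=False)


def reconstruct_from_summary(rate: float, n: int) -> int:
    """Recover an integer deposit count from a published rate and sample size.

    Returns ``round(rate * n)`` with round-half-to-even, computed in decimal
    so that printed two-decimal rates round deterministically (e.g. 0.59 x 50
    = 29.5 -> 30, unaffected by binary representation).
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    product = Decimal(repr(rate)) * n
    return int(product.quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))


#: Published per-cycle larval-deposition summaries:
#: (female, male, cycle, mean rate, SE, pooled n over three cages).
DEPOSITION_SUMMARY: tuple[tuple[FlyClass, FlyClass, int, float, float, int], ...] = (
    (W, W, 1, 0.68, 0.01, 108),
    (W, W, 2, 0.65, 0.07, 89),
    (W, A, 1, 0.87, 0.06, 59),
    (W, A, 2, 0.89, 0.16, 48),
    (A, A, 1, 0.61, 0.20, 49),
    (A, A, 2, 0.53, 0.18, 26),
    (A, W, 1, 0.10, 0.02, 44),
    (A, W, 2, 0.00, 0.00, 38),
    (M, M, 1, 0.68, 0.14, 53),
    (M, M, 2, 0.59, 0.07, 50),
)


def table1_fixture() -> CrossDataset:
    """The packaged deposition dataset reconstructed from published summaries.

    Per-cage replicate counts were not published (only mean rate +/- SE over
    three cages and the pooled number of females per cycle), so each cross x
    cycle is represented by a single pooled pseudo-cage with
    ``n_deposits = round(rate * n)`` (half-to-even).  This is an
    approximation of the underlying cage-level records.
    """
    observations = tuple(
        CrossObservation(
            female=f,
            male=m,
            cycle=cycle,
            cage_id="pooled",
            n_females=n,
            n_deposits=reconstruct_from_summary(rate, n),
        )
        for f, m, cycle, rate, _se, n in DEPOSITION_SUMMARY
    )
    return CrossDataset(observations, provenance="table1_fixture")


def table2_eclosion() -> pd.DataFrame:
    """Published pupal-eclosion summaries (packaged for completeness).

    Eclosion feeds no model here; the source study analyzed it with ANOVA
    only, and no eclosion term enters the deposition likelihood.
    """
    from importlib.resources import files

    with (files("cidrive.data") / "table2_eclosion.csv").open() as handle:
        return pd.read_csv(handle)
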