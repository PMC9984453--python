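"""Boundary registry, genes, time classes and developmental stages.

Six gap genes (*gt*, *hb*, *Kr*, *kni*, *otd*, *tll*) are expressed in broad
domains along the anterior-posterior (AP) axis of the blastoderm embryo.
A domain flank where expression crosses 50% of the domain's peak defines a
named boundary; 20 such boundaries form a fixed AP registry shared by all
lines.  Positions are fractional embryo length xi = x/L, anterior pole at
xi = 0.

The registry order is expressed as a chain of groups; boundaries inside one
group abut each other (e.g. ``hb2``/``Kr1`` near mid-embryo) and carry no
mutual order constraint, while every member of an earlier group lies
anterior to every member of a later group.  The two anterior *gt*
boundaries (``gt1``, ``gt2``) only become detectable late (from T5) and are
not part of the printed chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

GENES: tuple[str, ...] = ("gt", "hb", "Kr", "kni", "otd", "tll")

#: 10 time classes: nuclear cycle 13 plus nine subdivisions of nc14.
TIME_CLASSES: tuple[str, ...] = (
    "nc13", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
)

#: ordinal index used for trajectory interpolation (nc13 = 0, T9 = 9)
TIME_INDEX: dict[str, int] = {t: i for i, t in enumerate(TIME_CLASSES)}

RISING = "rising"
FALLING = "falling"


@dataclass(frozen=True)
class Boundary:
    """A named expression boundary: which gene, and which flank polarity.

    ``rising`` marks the anterior flank of a domain (expression increases
    with xi), ``falling`` the posterior flank.
    """

    name: str
    gene: str
    polarity: str


def _b(name: str, gene: str, polarity: str) -> tuple[str, Boundary]:
    return name, Boundary(name, gene, polarity)


#: the 20-name registry, keyed by boundary name
BOUNDARIES: dict[str, Boundary] = dict(
    (
        _b("gt1", "gt", RISING),
        _b("gt2", "gt", FALLING),
        _b("gt3", "gt", RISING),
        _b("gt4", "gt", FALLING),
        _b("gt5", "gt", RISING),
        _b("gt6", "gt", FALLING),
        _b("hb1", "hb", RISING),
        _b("hb2", "hb", FALLING),
        _b("hb3", "hb", RISING),
        _b("hb4", "hb", FALLING),
        _b("Kr1", "Kr", RISING),
        _b("Kr2", "Kr", FALLING),
        _b("kni1", "kni", FALLING),
        _b("kni2", "kni", RISING),
        _b("kni3", "kni", FALLING),
        _b("otd1", "otd", RISING),
        _b("otd2", "otd", FALLING),
        _b("tll1", "tll", RISING),
        _b("tll2", "tll", FALLING),
        _b("tll3", "tll", RISING),
    )
)

#: printed AP order; tuples group abutting boundaries with no mutual order
REGISTRY_CHAIN: tuple[tuple[str, ...], ...] = (
    ("kni1",),
    ("otd1",),
    ("tll1",),
    ("hb1", "gt3"),
    ("tll2",),
    ("otd2",),
    ("gt4",),
    ("hb2", "Kr1"),
    ("Kr2", "kni2"),
    ("kni3", "gt5"),
    ("gt6", "hb3"),
    ("tll3",),
    ("hb4",),
)

#: expression-domain structure per gene as (anterior flank, posterior flank);
#: ``None`` means the domain runs to the corresponding pole, so that flank
#: never crosses half-maximum and carries no name.
GENE_DOMAINS: dict[str, tuple[tuple[str | None, str | None], ...]] = {
    "gt": (("gt1", "gt2"), ("gt3", "gt4"), ("gt5", "gt6")),
    "hb": (("hb1", "hb2"), ("hb3", "hb4")),
    "Kr": (("Kr1", "Kr2"),),
    "kni": ((None, "kni1"), ("kni2", "kni3")),
    "otd": (("otd1", "otd2"),),
    "tll": (("tll1", "tll2"), ("tll3", None)),
}

#: the six boundaries anterior of xi = 0.3 used in the early/late
#: anterior-group comparison
ANTERIOR_BOUNDARIES: tuple[str, ...] = (
    "kni1", "otd1", "tll1", "gt3", "tll2", "otd2",
)


@dataclass(frozen=True)
class StageDefinition:
    """Grouping of time classes into initial / intermediate / final stages.

    T3, T6 and T7 belong to no stage; they separate the stages in time.
    """

    initial: frozenset[str] = frozenset({"nc13", "T1", "T2"})
    intermediate: frozenset[str] = frozenset({"T4", "T5"})
    final: frozenset[str] = frozenset({"T8", "T9"})

    def __post_init__(self) -> None:
        if (
            self.initial & self.intermediate
            or self.initial & self.final
            or self.intermediate & self.final
        ):
            raise ValueError("stage time-class sets must be disjoint")

    def classes(self, stage: str) -> frozenset[str]:
        """Return the time classes of stage ``'i'``, ``'m'`` or ``'f'``."""
        try:
            return {
                "i": self.initial,
                "initial": self.initial,
                "m": self.intermediate,
                "intermediate": self.intermediate,
                "f": self.final,
                "final": self.final,
            }[stage]
        except KeyError:
            raise KeyError(f"unknown stage {stage!r}; use 'i', 'm' or 'f'") from None


DEFAULT_STAGES = StageDefinition()


def registry_violations(
    positions: Mapping[str, float],
    chain: Sequence[Iterable[str]] = REGISTRY_CHAIN,
) -> list[tuple[str, str]]:
    """Check a set of boundary positions against the AP registry order.

    Parameters
    ----------
    positions
        Map of boundary name to xi.  Names absent from the map are skipped
        (a boundary may be undetectable at a given time class).

    Returns
    -------
    list of (anterior_name, posterior_name) pairs whose order is violated,
    i.e. the nominally anterior boundary was found at a larger xi.
    """
    groups = [
        [(n, positions[n]) for n in grp if n in positions] for grp in chain
    ]
    groups = [g for g in groups if g]
    bad: list[tuple[str, str]] = []
    for left, right in zip(groups, groups[1:]):
        la, lxi = max(left, key=lambda p: p[1])
        ra, rxi = min(right, key=lambda p: p[1])
        if lxi >= rxi:
            bad.append((la, ra))
    return bad


def ordered_boundaries(positions: Mapping[str, float]) -> list[str]:
    """Boundary names sorted by xi (ties broken by registry definition order)."""
    order = {n: i for i, n in enumerate(BOUNDARIES)}
    return sorted(positions, key=lambda n: (positions[n], order.get(n, 99)))
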