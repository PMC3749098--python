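"""Evolutionary timelines: node distances, molecular clocks, coevolution.

The relative age of a leaf in a rooted tree of domain structures is its
node distance ``nd``: the number of nodes traversed from the root to the
leaf, rescaled to [0, 1] so the earliest-diverging lineage sits at 0 and
the deepest at 1.  Calibrated linear molecular clocks convert ``nd`` to
geological time in billions of years (Gy):

    fold level (F):              t = -3.802 * nd + 3.814
    fold-superfamily level (FSF): t = -3.831 * nd + 3.628

Age-age regressions between aaRS domain ages (nd) and tRNA group ages
(constraint steps S) quantify coevolution of the two molecular partners.
Group partitions of the 20 amino acids track the inferred order of
genetic-code expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .parsimony import RootedTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: aaRS age groups: Group 1 = ancient editing domains charging the basal
#: type II tRNAs (Tyr, Ser, Leu); Group 2 = editing domains for type I
#: tRNAs; Group 3 = recent anticodon-binding domains.
GROUP_123 = {
    "1": frozenset("YSL"),
    "2": frozenset("KFPTAMIV"),
    "3": frozenset("EQRCGWNDH"),
}

#: Genetic-code expansion stages from the idealized anticodon-interaction
#: timeline: A (earliest; class IIa anticodon-binding), B (class Ia/Ib),
#: C (late recruitments).
GROUP_ABC = {
    "A": frozenset("PATGH"),
    "B": frozenset("VMICQRL"),
    "C": frozenset("DNKSEYFW"),
}


def _validate_partition(tables: dict[str, frozenset[str]], universe: str = AMINO_ACIDS):
    seen: dict[str, str] = {}
    for name, members in tables.items():
        for aa in members:
            if aa in seen:
                raise ValueError(f"residue {aa} assigned to groups {seen[aa]} and {name}")
            seen[aa] = name
    missing = set(universe) - set(seen)
    if missing:
        raise ValueError(f"partition does not cover residues: {sorted(missing)}")


_validate_partition(GROUP_123)
_validate_partition(GROUP_ABC)


@dataclass
class ClockSpec:
    """Linear molecular clock t = slope * nd + intercept (Gy)."""

    slope: float
    intercept: float
    level: str

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("clock slope must be negative (age decreases with nd)")


#: Published clock calibrations at fold (F) and fold-superfamily (FSF) levels.
CLOCK_F = ClockSpec(slope=-3.802, intercept=3.814, level="F")
CLOCK_FSF = ClockSpec(slope=-3.831, intercept=3.628, level="FSF")


@dataclass
class TimelineEntry:
    domain_id: str
    nd: float
    age_gy: float | None = None
    group123: str = "unassigned"
    groupABC: str = "unassigned"


@dataclass
class CoevolutionPoint:
    """One aaRS domain: its age (nd) and its tRNA partner's age (S steps)."""

    domain_id: str
    nd: float
    s: float
    role: str = "catalytic"


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float | None
    r2: float
    f: float
    p: float
    n: int
    through_origin: bool


def compute_nd(tree: RootedTree) -> dict[str, float]:
    """Node distance of every leaf: scaled root-to-leaf node count.

    ``nd = (depth - min depth) / (max depth - min depth)`` where depth is
    the number of nodes (edges) on the root-to-leaf path.  The earliest-
    diverging leaf anchors at 0; the deepest at 1.  If all leaves are
    equidistant from the root (a perfectly balanced tree) every nd is 0
    and a warning is issued — such trees carry no relative age signal.
    """
    depths = tree.depths()
    if not depths:
        raise ValueError("tree has no leaves")
    values = np.array(list(depths.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("all leaves equidistant from root; nd set to 0 for all")
        return {leaf: 0.0 for leaf in depths}
    return {leaf: (d - lo) / (hi - lo) for leaf, d in depths.items()}


def clock_age(nd: float, clock: ClockSpec = CLOCK_F) -> float:
    """Convert a node distance to a geological age in Gy before present.

    Ages past the calibration range (nd near 1 at the F level) would be
    negative; they are clamped to 0 with a warning.
    """
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd must be in [0, 1], got {nd}")
    age = clock.slope * nd + clock.intercept
    if age < 0:
        warnings.warn(f"clock age {age:.3f} Gy at nd={nd} clamped to 0")
        return 0.0
    return age


def assign_groups(
    entries: list[TimelineEntry],
    amino_acid_of: dict[str, str],
    group123: dict[str, frozenset[str]] | None = None,
    groupABC: dict[str, frozenset[str]] | None = None,
) -> list[TimelineEntry]:
    """Attach age-group and expansion-stage labels to timeline entries.

    ``amino_acid_of`` maps each domain id to the one-letter code of the
    amino acid its aaRS charges; domains whose residue is absent from a
    partition (or unmapped domains) are labeled ``unassigned``.
    """
    g123 = group123 or GROUP_123
    gABC = groupABC or GROUP_ABC
    _validate_partition(g123)
    _validate_partition(gABC)
    lookup123 = {aa: name for name, members in g123.items() for aa in members}
    lookupABC = {aa: name for name, members in gABC.items() for aa in members}
    for entry in entries:
        aa = amino_acid_of.get(entry.domain_id)
        if aa is None:
            continue
        entry.group123 = lookup123.get(aa, "unassigned")
        entry.groupABC = lookupABC.get(aa, "unassigned")
    return entries


def coevolution_regression(
    points: list[CoevolutionPoint], through_origin: bool = True
) -> RegressionResult:
    """Least-squares fit of tRNA age (S) on aaRS domain age (nd).

    Through-origin mode (S = b * nd) uses b = sum(xy)/sum(x^2), the
    uncentered R^2 and F = (n-1) R^2 / (1-R^2) on (1, n-1) df — the form
    matching a slope-only coevolution model where a domain of age 0 pairs
    with the oldest (S = 0) tRNA.  Intercept mode is ordinary simple
    regression with F on (1, n-2) df.
    """
    if len(points) < 3:
        raise ValueError("regression needs at least 3 points")
    x = np.array([p.nd for p in points], dtype=float)
    y = np.array([p.s for p in points], dtype=float)
    n = len(x)
    if np.allclose(x, x[0]):
        raise ValueError("all nd values identical; slope undefined")

    if through_origin:
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        df = n - 1
        sigma2 = float(resid @ resid) / df
        slope_se = np.sqrt(sigma2 / sxx)
        syy = float(y @ y)
        r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 0.0
        f = df * r2 / (1.0 - r2) if r2 < 1.0 else np.inf
        p = float(sps.f.sf(f, 1, df))
        return RegressionResult(slope, float(slope_se), None, float(r2),
                                float(f), p, n, True)

    fit = sps.linregress(x, y)
    r2 = fit.rvalue**2
    df = n - 2
    f = df * r2 / (1.0 - r2) if r2 < 1.0 else np.inf
    p = float(sps.f.sf(f, 1, df))
    return RegressionResult(float(fit.slope), float(fit.stderr),
                            float(fit.intercept), float(r2), float(f), p, n, False)


def build_timeline(
    tree: RootedTree, clock: ClockSpec = CLOCK_F
) -> list[TimelineEntry]:
    """Node distances + clock ages for every leaf of a rooted domain tree."""
    nd = compute_nd(tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            TimelineEntry(domain_id=leaf, nd=v, age_gy=clock_age(v, clock))
            for leaf, v in sorted(nd.items(), key=lambda kv: kv[1])
        ]


def write_timeline(entries: list[TimelineEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("domain_id\tnd\tage_gy\tgroup123\tgroupABC\n")
        for e in entries:
            age = f"{e.age_gy:.4f}" if e.age_gy is not None else "NA"
            fh.write(f"{e.domain_id}\t{e.nd:.6f}\t{age}\t{e.group123}\t{e.groupABC}\n")
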