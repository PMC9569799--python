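"""Synthetic DSB damage generation and complexity classification.

A double-strand break (DSB) is a pair of opposing-strand breaks lying
within a short stretch of the double helix.  A DSB is *complex* when at
least one additional strand break sits on either strand within a small
window of the break site; complex DSBs are the hallmark of densely
ionising (high-LET) radiation and are channelled into the slow,
resection-dependent end-joining compartment.

This module replaces a full Monte Carlo track-structure chain with a
parametric generator: DSB counts are Poisson in dose, positions uniform
in a spherical nucleus, and complexity / chromatin labels are
independent Bernoulli draws.  It also provides the break-pattern
classifier used when explicit strand-break lists are available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Strand",
    "Complexity",
    "Chromatin",
    "Pathway",
    "StrandBreak",
    "DSBRecord",
    "DamageSet",
    "generate_damage",
    "detect_and_classify",
    "read_damage_tsv",
    "write_damage_tsv",
]


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class Complexity(str, enum.Enum):
    SIMPLE = "simple"
    COMPLEX = "complex"


class Chromatin(str, enum.Enum):
    EC = "EC"  # euchromatin
    HC = "HC"  # heterochromatin


class Pathway(str, enum.Enum):
    UNASSIGNED = "unassigned"
    FAST = "fast"  # resection-independent NHEJ
    SLOW = "slow"  # resection-dependent NHEJ


@dataclass(frozen=True)
class StrandBreak:
    """A single-strand break at an integer base-pair position."""

    chromosome_id: int
    position: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))


@dataclass
class DSBRecord:
    """One double-strand break with spatial and repair-relevant labels."""

    id: int
    coord: np.ndarray  # (3,) nm, inside the nucleus sphere
    complexity: Complexity
    chromatin: Chromatin
    pathway: Pathway = Pathway.UNASSIGNED
    breaks: list[StrandBreak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("coord must be a 3-vector")
        self.complexity = Complexity(self.complexity)
        self.chromatin = Chromatin(self.chromatin)
        self.pathway = Pathway(self.pathway)


@dataclass
class DamageSet:
    """A collection of DSBs plus the exposure metadata that produced it."""

    dsbs: list[DSBRecord]
    dose: float = 0.0  # Gy
    dsb_yield: float = 40.0  # DSB per Gy per cell
    complex_fraction: float = 0.0
    hc_fraction: float = 0.0
    nucleus_radius: float = 5000.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("complex_fraction", "hc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")

    def __len__(self) -> int:
        return len(self.dsbs)

    def coords(self) -> np.ndarray:
        if not self.dsbs:
            return np.empty((0, 3))
        return np.stack([d.coord for d in self.dsbs])

    def pathways(self) -> np.ndarray:
        return np.array([d.pathway.value for d in self.dsbs])

    def copy(self) -> "DamageSet":
        return replace(self, dsbs=[replace(d, coord=d.coord.copy()) for d in self.dsbs])


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a ball: isotropic direction x cube-root radius."""
    direction = rng.normal(size=(n, 3))
    norm = np.linalg.norm(direction, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction / norm * r[:, None]


def generate_damage(
    dose: float,
    dsb_yield: float = 40.0,
    complex_fraction: float = 0.1,
    hc_fraction: float = 0.2,
    nucleus_radius: float = 5000.0,
    seed: int = 0,
) -> DamageSet:
    """Draw a synthetic damage set for a given dose.

    The DSB count is Poisson with mean ``dose * dsb_yield``; positions
    are uniform in the nucleus sphere; complexity and chromatin labels
    are independent Bernoulli draws with the given fractions.

    Parameters
    ----------
    dose : float
        Absorbed dose in Gy.
    dsb_yield : float
        Mean DSBs per Gy per cell (~40 for mammalian cells).
    complex_fraction : float
        Probability that a DSB is complex; rises with LET.
    hc_fraction : float
        Probability that a DSB lies in heterochromatin.
    nucleus_radius : float
        Radius of the spherical nucleus in nm.
    seed : int
        RNG seed; fixed seed gives an identical damage set.
    """
    if dose < 0 or dsb_yield < 0 or nucleus_radius < 0:
        raise ValueError("dose, dsb_yield and nucleus_radius must be >= 0")
    for name, v in (("complex_fraction", complex_fraction), ("hc_fraction", hc_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(dose * dsb_yield))
    coords = _uniform_in_sphere(rng, n, nucleus_radius)
    is_complex = rng.random(n) < complex_fraction
    in_hc = rng.random(n) < hc_fraction
    dsbs = [
        DSBRecord(
            id=i,
            coord=coords[i],
            complexity=Complexity.COMPLEX if is_complex[i] else Complexity.SIMPLE,
            chromatin=Chromatin.HC if in_hc[i] else Chromatin.EC,
        )
        for i in range(n)
    ]
    return DamageSet(
        dsbs=dsbs,
        dose=dose,
        dsb_yield=dsb_yield,
        complex_fraction=complex_fraction,
        hc_fraction=hc_fraction,
        nucleus_radius=nucleus_radius,
        seed=seed,
    )


def detect_and_classify(
    breaks: list[StrandBreak], window_bp: int = 10
) -> list[DSBRecord]:
    """Pair opposing-strand breaks into DSBs and grade their complexity.

    Breaks are sorted by (chromosome, position).  Scanning left to
    right, each forward-strand break pairs greedily with the nearest
    unused reverse-strand break within ``window_bp`` on the same
    chromosome (and vice versa); each break is used at most once.  A DSB
    is *complex* iff at least one additional (unpaired or other-DSB)
    break lies within ``window_bp`` (inclusive) of the DSB midpoint, and
    *simple* otherwise.

    The returned records carry placeholder coordinates at the origin;
    chromatin defaults to euchromatin since break lists carry no
    chromatin information.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")

    ordered = sorted(breaks, key=lambda b: (b.chromosome_id, b.position, b.strand.value))
    used = [False] * len(ordered)
    pairs: list[tuple[int, int]] = []

    for i, b in enumerate(ordered):
        if used[i]:
            continue
        # nearest opposing-strand partner within the window, not yet used
        best_j = -1
        best_dist = window_bp + 1
        for j, other in enumerate(ordered):
            if j == i or used[j]:
                continue
            if other.chromosome_id != b.chromosome_id or other.strand == b.strand:
                continue
            dist = abs(other.position - b.position)
            if dist <= window_bp and (
                dist < best_dist or (dist == best_dist and j < best_j)
            ):
                best_dist = dist
                best_j = j
        if best_j >= 0:
            used[i] = used[best_j] = True
            pairs.append((i, best_j))

    records: list[DSBRecord] = []
    for dsb_id, (i, j) in enumerate(pairs):
        b1, b2 = ordered[i], ordered[j]
        midpoint = (b1.position + b2.position) / 2.0
        extra = any(
            k not in (i, j)
            and ordered[k].chromosome_id == b1.chromosome_id
            and abs(ordered[k].position - midpoint) <= window_bp
            for k in range(len(ordered))
        )
        records.append(
            DSBRecord(
                id=dsb_id,
                coord=np.zeros(3),
                complexity=Complexity.COMPLEX if extra else Complexity.SIMPLE,
                chromatin=Chromatin.EC,
                breaks=[b1, b2],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Simplified SDD-like exchange format: TSV with one DSB per row.

_DAMAGE_COLUMNS = ["id", "x_nm", "y_nm", "z_nm", "complexity", "chromatin"]


def write_damage_tsv(damage: DamageSet, path) -> None:
    df = pd.DataFrame(
        {
            "id": [d.id for d in damage.dsbs],
            "x_nm": [d.coord[0] for d in damage.dsbs],
            "y_nm": [d.coord[1] for d in damage.dsbs],
            "z_nm": [d.coord[2] for d in damage.dsbs],
            "complexity": [d.complexity.value for d in damage.dsbs],
            "chromatin": [d.chromatin.value for d in damage.dsbs],
            "pathway": [d.pathway.value for d in damage.dsbs],
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# dose_gy={damage.dose} dsb_yield={damage.dsb_yield} "
            f"complex_fraction={damage.complex_fraction} "
            f"hc_fraction={damage.hc_fraction} "
            f"nucleus_radius_nm={damage.nucleus_radius} seed={damage.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_damage_tsv(path) -> DamageSet:
    meta: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for token in header[1:].split():
                key, _, val = token.partition("=")
                meta[key] = float(val)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    missing = set(_DAMAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"damage file missing columns: {sorted(missing)}")
    has_pathway = "pathway" in df.columns
    dsbs = [
        DSBRecord(
            id=int(row.id),
            coord=np.array([row.x_nm, row.y_nm, row.z_nm]),
            complexity=Complexity(row.complexity),
            chromatin=Chromatin(row.chromatin),
            pathway=Pathway(row.pathway) if has_pathway else Pathway.UNASSIGNED,
        )
        for row in df.itertuples()
    ]
    return DamageSet(
        dsbs=dsbs,
        dose=meta.get("dose_gy", 0.0),
        dsb_yield=meta.get("dsb_yield", 40.0),
        complex_fraction=meta.get("complex_fraction", 0.0),
        hc_fraction=meta.get("hc_fraction", 0.0),
        nucleus_radius=meta.get("nucleus_radius_nm", 5000.0),
        seed=int(meta.get("seed", 0)),
    )
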