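"""The 61 primary biochemical descriptors and min-max normalization.

Each peptide is described by a fixed 61-dimensional vector of primary
physicochemical properties: length, charge features, isoelectric point,
molecular weight, grand-average hydropathy, the 20 per-residue counts and
20 per-residue percentages, four residue-group percentages, five
mean-per-residue property scales, net donated side-chain hydrogen bonds,
and the three secondary-structure state fractions. Property scales live in
a JSON registry (``data/scales.json``) with citations and can be swapped;
the defaults are the standard published scales named there.

Residue grouping partitions the alphabet: positive {K,R,H} (histidine is
counted as positive), negative {D,E}, polar-uncharged {S,T,N,Q,Y,C}, and
hydrophobic {A,V,L,I,M,F,W,P,G}. Terminal groups are excluded from the
integer charge counts but included in the isoelectric-point titration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInput
from .peptides import ALPHABET, Peptide, PeptideCollection

# ---------------------------------------------------------------------------
# scale registry

with resources.files("cppscreen.data").joinpath("scales.json").open() as _fh:
    _REGISTRY = json.load(_fh)


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue property scale with provenance."""

    name: str
    values: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if not all(np.isfinite(list(self.values.values()))):
            raise ValueError(f"scale {self.name!r} has non-finite entries")


def get_scale(name: str) -> ResidueScale:
    """Look up a scale from the packaged registry by name."""
    entry = _REGISTRY["scales"][name]
    return ResidueScale(name, entry["values"], entry["citation"])


RESIDUE_GROUPS = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQYC"),
    "hydrophobic": frozenset("AVLIMFWPG"),
}

_HBOND = _REGISTRY["hbond"]["values"]
_MASS = _REGISTRY["mass"]["values"]
_WATER = _REGISTRY["mass"]["water"]
_CF = _REGISTRY["chou_fasman"]
_PKA = _REGISTRY["pka"]

#: canonical feature order; exactly 61 names
FEATURE_NAMES: tuple[str, ...] = (
    "length", "net_charge", "positive_charge", "negative_charge",
    "isoelectric_point", "molecular_weight", "hydropathicity",
    *[f"count_{a}" for a in ALPHABET],
    *[f"percent_{a}" for a in ALPHABET],
    "percent_polar", "percent_positive", "percent_negative",
    "percent_hydrophobic",
    "hydrophobicity", "lipophilicity", "amphiphilicity",
    "water_octanol_partition", "steric_bulk", "side_chain_bulk",
    "net_donated_hbonds",
    "percent_helix", "percent_coil", "percent_sheet",
)
assert len(FEATURE_NAMES) == 61


# ---------------------------------------------------------------------------
# individual descriptor operations

def aa_composition(p: Peptide) -> tuple[dict[str, int], dict[str, float]]:
    """Per-residue counts and percentages (counts sum to the length)."""
    n = len(p)
    counts = {a: p.sequence.count(a) for a in ALPHABET}
    percents = {a: 100.0 * c / n for a, c in counts.items()}
    return counts, percents


def charge_features(p: Peptide) -> tuple[int, int, int]:
    """(positive, negative, net) side-chain charge counts.

    Positive counts K, R and H; negative counts D and E; termini excluded.
    """
    pos = sum(p.sequence.count(a) for a in "KRH")
    neg = sum(p.sequence.count(a) for a in "DE")
    return pos, neg, pos - neg


def _net_charge_at_ph(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of termini plus ionizable side chains."""
    basic = set(_PKA["basic"])

    def positive(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def negative(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    q = positive(_PKA["nterm"]) + negative(_PKA["cterm"])
    for res, pka in _PKA["sidechain"].items():
        n = seq.count(res)
        if n:
            q += n * (positive(pka) if res in basic else negative(pka))
    return q


def isoelectric_point(p: Peptide, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, found by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique; the EMBOSS pKa set is used (see the packaged registry).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge_at_ph(p.sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight(p: Peptide) -> float:
    """Average molecular mass in Da, free acid/amine termini (one water)."""
    return sum(_MASS[a] for a in p.sequence) + _WATER


def scale_mean(p: Peptide, scale: ResidueScale) -> float:
    """Arithmetic mean of per-residue scale values (GRAVY convention)."""
    return sum(scale.values[a] for a in p.sequence) / len(p)


def gravy(p: Peptide) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    return scale_mean(p, get_scale("hydropathicity"))


def net_donated_hbonds(p: Peptide) -> float:
    """Sum of side-chain (donor - acceptor) counts; backbone excluded."""
    return float(sum(_HBOND[a] for a in p.sequence))


def secondary_structure_fractions(p: Peptide) -> tuple[float, float, float]:
    """(helix%, sheet%, coil%) by per-residue propensity argmax.

    Each residue is assigned the state with the highest Chou-Fasman
    propensity; ties break in the fixed order helix > sheet > coil so the
    assignment is deterministic. Fractions sum to 100.
    """
    n = len(p)
    states = {"helix": 0, "sheet": 0, "coil": 0}
    for a in p.sequence:
        best = max(("helix", "sheet", "coil"), key=lambda s: (_CF[s][a],
                   {"helix": 2, "sheet": 1, "coil": 0}[s]))
        states[best] += 1
    return tuple(100.0 * states[s] / n for s in ("helix", "sheet", "coil"))


def group_percents(p: Peptide) -> dict[str, float]:
    """Percentage of residues in each of the four exclusive groups."""
    n = len(p)
    return {g: 100.0 * sum(1 for a in p.sequence if a in members) / n
            for g, members in RESIDUE_GROUPS.items()}


def compute_feature_vector(p: Peptide) -> np.ndarray:
    """All 61 descriptors in canonical :data:`FEATURE_NAMES` order."""
    counts, percents = aa_composition(p)
    pos, neg, net = charge_features(p)
    groups = group_percents(p)
    helix, sheet, coil = secondary_structure_fractions(p)
    vec = [
        float(len(p)), float(net), float(pos), float(neg),
        isoelectric_point(p), molecular_weight(p), gravy(p),
        *[float(counts[a]) for a in ALPHABET],
        *[percents[a] for a in ALPHABET],
        groups["polar"], groups["positive"], groups["negative"],
        groups["hydrophobic"],
        scale_mean(p, get_scale("hydrophobicity")),
        scale_mean(p, get_scale("lipophilicity")),
        scale_mean(p, get_scale("amphiphilicity")),
        scale_mean(p, get_scale("water_octanol_partition")),
        scale_mean(p, get_scale("steric_bulk")),
        scale_mean(p, get_scale("side_chain_bulk")),
        net_donated_hbonds(p),
        helix, coil, sheet,
    ]
    return np.asarray(vec, dtype=float)


def feature_table(collection: PeptideCollection | Sequence[Peptide]) -> pd.DataFrame:
    """Feature matrix for a collection, indexed by peptide id."""
    peps = list(collection)
    if not peps:
        raise EmptyInput("cannot featurize an empty collection")
    X = np.vstack([compute_feature_vector(p) for p in peps])
    return pd.DataFrame(X, index=[p.id for p in peps], columns=list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# min-max normalization to [0, 1]

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training minima/maxima for [0, 1] rescaling."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ValueError("normalization max < min")


def fit_normalizer(X: np.ndarray) -> NormalizationParams:
    """Learn per-column min/max from a training matrix."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise EmptyInput("cannot fit a normalizer on an empty matrix")
    return NormalizationParams(X.min(axis=0), X.max(axis=0))


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Scale columns to [0, 1]; constant columns map to 0, held-out values
    outside the training range are clamped."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise EmptyInput("cannot normalize an empty matrix")
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (X - params.minimum) / safe
    scaled[:, span == 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)
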