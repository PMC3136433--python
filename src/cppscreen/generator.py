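"""Random peptide generation from a 0th-order Markov (i.i.d. residue) model.

Candidate peptides are sampled residue-by-residue from a fixed amino-acid
frequency vector, with lengths drawn uniformly from an inclusive range
(default 12-26, the size range of the compiled CPP tables). A packaged
proteome-scale background frequency table is the default model;
``estimate_frequencies`` derives a model from any user-supplied proteome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import EmptyInput, InvalidModel
from .peptides import ALPHABET, Label, Peptide, PeptideCollection, read_fasta


@dataclass(frozen=True)
class ResidueFrequencyModel:
    """Amino-acid frequencies plus the uniform length range to sample."""

    frequencies: dict[str, float]
    source: str = ""
    length_range: tuple[int, int] = (12, 26)

    def __post_init__(self) -> None:
        if set(self.frequencies) != set(ALPHABET):
            raise InvalidModel("frequency table must cover the 20 residues")
        total = sum(self.frequencies.values())
        if any(v < 0 for v in self.frequencies.values()) or total <= 0:
            raise InvalidModel("frequencies must be non-negative with positive sum")
        if abs(total - 1.0) > 1e-9:
            raise InvalidModel(f"frequencies sum to {total}, not 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise InvalidModel(f"bad length range {self.length_range}")

    def as_array(self) -> np.ndarray:
        return np.array([self.frequencies[a] for a in ALPHABET])


def default_frequency_model(length_range: tuple[int, int] = (12, 26)) -> ResidueFrequencyModel:
    """The packaged proteome-scale background composition."""
    with resources.files("cppscreen.data").joinpath("frequencies.json").open() as fh:
        data = json.load(fh)
    freq = data["frequencies"]
    total = sum(freq.values())
    freq = {a: v / total for a, v in freq.items()}
    return ResidueFrequencyModel(freq, source=data["citation"],
                                 length_range=length_range)


def estimate_frequencies(proteome: PeptideCollection | str | Path,
                         length_range: tuple[int, int] = (12, 26)) -> ResidueFrequencyModel:
    """Empirical residue frequencies from a collection or FASTA file."""
    if not isinstance(proteome, PeptideCollection):
        proteome = read_fasta(proteome)
    if len(proteome) == 0:
        raise EmptyInput("empty proteome")
    counts = {a: 0 for a in ALPHABET}
    total = 0
    for p in proteome:
        for a in p.sequence:
            counts[a] += 1
        total += len(p)
    freq = {a: c / total for a, c in counts.items()}
    return ResidueFrequencyModel(freq, source=f"estimated from {proteome.name or 'input'}",
                                 length_range=length_range)


def sample_peptides(model: ResidueFrequencyModel, n: int, seed: int | np.random.Generator,
                    prefix: str = "rand", label: Label = Label.UNKNOWN) -> PeptideCollection:
    """Draw ``n`` i.i.d. peptides from the model, reproducibly.

    Lengths are uniform on the inclusive range; residues are independent
    draws from the frequency vector. ``seed`` may be an integer or an
    existing :class:`numpy.random.Generator` (consumed in place).
    """
    if n < 1:
        raise EmptyInput("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    probs = model.as_array()
    probs = probs / probs.sum()
    lo, hi = model.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    peps = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=int(L), p=probs))
        peps.append(Peptide(f"{prefix}_{i+1:04d}", seq, label=label,
                            source=f"sampled from {model.source or 'frequency model'}"))
    return PeptideCollection(peps, name=f"{prefix}_n{n}")
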