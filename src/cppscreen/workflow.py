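"""End-to-end candidate screening: generate, featurize, classify, rank.

Mirrors the computational validation design: sample candidate peptides
from the background frequency model, classify each with a trained PUK-SVM,
rank all candidates by decision value, and shortlist the strongest
predicted penetrators together with the strongest predicted
non-penetrators for synthesis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ShortlistUnderflow
from .generator import ResidueFrequencyModel, sample_peptides
from .peptides import Label, Peptide
from .svm import PukSvmResults


@dataclass
class ScreeningResult:
    """Ranked candidates plus the synthesis shortlist and run manifest."""

    table: pd.DataFrame            # id, sequence, label, decision, rank
    shortlist_positive: list[str]  # candidate ids, strongest CPP first
    shortlist_negative: list[str]  # candidate ids, strongest non-CPP first
    manifest: dict = field(default_factory=dict)
    underflow: bool = False

    @property
    def n_predicted_cpp(self) -> int:
        return int((self.table["label"] == "CPP").sum())

    @property
    def n_predicted_noncpp(self) -> int:
        return int((self.table["label"] == "NON_CPP").sum())


def screen_candidates(results: PukSvmResults,
                      model: ResidueFrequencyModel,
                      n: int = 250,
                      seed: int = 0,
                      shortlist: tuple[int, int] = (4, 2)) -> ScreeningResult:
    """Generate ``n`` candidates and rank them by decision value.

    The shortlist takes the ``shortlist[0]`` highest-scoring predicted
    CPPs and the ``shortlist[1]`` lowest-scoring predicted non-CPPs. If a
    class has fewer predictions than requested the shortlist is truncated
    and the result flagged (``underflow=True``) rather than failing the
    whole screen.
    """
    n_pos_wanted, n_neg_wanted = shortlist
    if n < max(n_pos_wanted, n_neg_wanted):
        raise ShortlistUnderflow(f"cannot shortlist {shortlist} from n={n}")
    candidates = sample_peptides(model, n, seed, prefix="cand")
    labels, scores = results.predict_peptides(list(candidates))
    order = np.argsort(-scores, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame({
        "id": [p.id for p in candidates],
        "sequence": [p.sequence for p in candidates],
        "label": [l.value for l in labels],
        "decision": scores,
        "rank": rank,
    }).sort_values("rank").reset_index(drop=True)

    pos = table[table["label"] == "CPP"]
    neg = table[table["label"] == "NON_CPP"]
    short_pos = list(pos["id"].head(n_pos_wanted))
    short_neg = list(neg.sort_values("decision")["id"].head(n_neg_wanted))
    underflow = len(short_pos) < n_pos_wanted or len(short_neg) < n_neg_wanted

    manifest = {
        "n_candidates": n,
        "generator_seed": seed,
        "generator_source": model.source,
        "length_range": list(model.length_range),
        "shortlist_requested": [n_pos_wanted, n_neg_wanted],
        "model_sha1": hashlib.sha1(results.to_json().encode()).hexdigest(),
        "counts": {"CPP": int((np.asarray([l.value for l in labels]) == "CPP").sum()),
                   "NON_CPP": int((np.asarray([l.value for l in labels]) == "NON_CPP").sum())},
    }
    return ScreeningResult(table=table, shortlist_positive=short_pos,
                           shortlist_negative=short_neg, manifest=manifest,
                           underflow=underflow)


def write_screening(result: ScreeningResult, tsv_path, manifest_path=None) -> None:
    """Write the ranked table as TSV and (optionally) the run manifest."""
    result.table.to_csv(tsv_path, sep="\t", index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump({**result.manifest,
                       "shortlist_positive": result.shortlist_positive,
                       "shortlist_negative": result.shortlist_negative},
                      fh, indent=1)
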