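"""Comparison of prior versions built from different database snapshots.

Two analyses:

* edge confusion matrix between two motif priors, restricted to the TFs
  present in both networks; the gene universe is the union of genes seen in
  either prior, so genes gained or lost between versions count as
  disagreement;
* per-TF binding-score shift between two track versions, as the difference
  of mean site scores (new minus old) per TF, optionally restricted to a
  scaffold subset (motif trimming between releases changes site coordinates,
  so sites are compared as per-TF score distributions, not matched pairs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .grn import MotifPriorEdges
from .sites import BindingSite

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Edge agreement counts over shared-TF x gene-universe pairs."""

    both: int
    only_a: int
    only_b: int
    neither: int
    shared_tfs: int
    gene_universe: int

    @property
    def total(self) -> int:
        return self.both + self.only_a + self.only_b + self.neither

    @property
    def disagreement_fraction(self) -> float:
        """Fraction of compared pairs present in exactly one prior."""
        return (self.only_a + self.only_b) / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "both": self.both,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "neither": self.neither,
            "shared_tfs": self.shared_tfs,
            "gene_universe": self.gene_universe,
        }


@dataclass
class ScoreShift:
    """Mean score change per TF (new minus old), in track score units."""

    per_tf: dict[str, float]
    region_restriction: Optional[set[str]] = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_tf.items()), columns=["tf_name", "mean_shift"]
        )


def edge_confusion(prior_a: MotifPriorEdges, prior_b: MotifPriorEdges) -> ConfusionMatrix:
    """Confusion matrix for edges of two priors, restricted to shared TFs.

    TFs present in only one prior are excluded entirely; the gene universe is
    the union of genes appearing in either prior.  Counts satisfy
    ``both + only_a + only_b + neither == shared_tfs * gene_universe``.
    """
    if prior_a.gene_key_kind != prior_b.gene_key_kind:
        raise ValueError("priors use different gene key kinds")
    shared = prior_a.tf_names & prior_b.tf_names
    universe = prior_a.gene_keys | prior_b.gene_keys
    if not shared:
        logger.warning("no TFs shared between the two priors: zero matrix")
        return ConfusionMatrix(0, 0, 0, 0, 0, len(universe))

    a = {(t, g) for t, g in prior_a.pairs if t in shared}
    b = {(t, g) for t, g in prior_b.pairs if t in shared}
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(shared) * len(universe) - both - only_a - only_b
    return ConfusionMatrix(both, only_a, only_b, neither, len(shared), len(universe))


def score_shift(
    sites_old: Iterable[BindingSite],
    sites_new: Iterable[BindingSite],
    restriction: Optional[set[str]] = None,
) -> ScoreShift:
    """Per-TF mean score change between two track versions.

    ``restriction`` optionally limits both versions to a scaffold subset.
    TFs with no site in either version (within the restriction) are omitted.
    Anti-symmetric: swapping old and new negates every value.
    """

    def collect(sites: Iterable[BindingSite]) -> dict[str, tuple[int, int]]:
        acc: dict[str, tuple[int, int]] = {}
        for s in sites:
            if restriction is not None and s.scaffold not in restriction:
                continue
            total, n = acc.get(s.tf_name, (0, 0))
            acc[s.tf_name] = (total + s.score, n + 1)
        return acc

    old = collect(sites_old)
    new = collect(sites_new)
    per_tf = {}
    for tf in old.keys() & new.keys():
        (so, no), (sn, nn) = old[tf], new[tf]
        # equal site counts: difference of sums is exact where the
        # difference of means would accumulate rounding error
        if no == nn:
            per_tf[tf] = (sn - so) / no
        else:
            per_tf[tf] = sn / nn - so / no
    return ScoreShift(per_tf, restriction)


def write_confusion_report(matrix: ConfusionMatrix, path: Union[str, Path]) -> None:
    """Write the confusion counts as a JSON report."""
    payload = matrix.to_dict()
    payload["disagreement_fraction"] = matrix.disagreement_fraction
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_shift_report(shift: ScoreShift, path: Union[str, Path]) -> None:
    """Write the per-TF shift table as a TSV."""
    shift.to_frame().to_csv(path, sep="\t", index=False)
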