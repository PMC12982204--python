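"""AOI-to-AOI transition matrices.

For each trial, the fixation sequence is taken in time order (saccades and
other events are skipped, but do not break the chain); each consecutive
fixation pair contributes one count for every ``(a, b)`` in the Cartesian
product of the two fixations' resolved AOI sets.  Transitions never cross
trial or participant boundaries.  Defaults follow the usual convention in
eye-movement transition analysis: self-transitions and the no-AOI
pseudo-label are excluded, with flags to include either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import GazeDataset, ViewFilter

__all__ = ["NO_AOI_LABEL", "TransitionMatrix", "transition_matrix"]

NO_AOI_LABEL = "(no AOI)"


@dataclass(frozen=True)
class TransitionMatrix:
    aoi_order: tuple
    counts: np.ndarray
    scope: ViewFilter = field(default_factory=ViewFilter)

    def __post_init__(self) -> None:
        assert self.counts.shape == (len(self.aoi_order), len(self.aoi_order))

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.counts[self.aoi_order.index(a), self.aoi_order.index(b)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path=None) -> str:
        """Square CSV with row/column labels and integer cells."""
        import csv
        import io

        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["from\\to", *self.aoi_order])
        for label, row in zip(self.aoi_order, self.counts):
            w.writerow([label, *(int(x) for x in row)])
        text = buf.getvalue()
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text, encoding="utf-8", newline="")
        return text


def transition_matrix(
    dataset: GazeDataset,
    *,
    include_self: bool = False,
    include_no_aoi: bool = False,
    scope: ViewFilter | None = None,
) -> TransitionMatrix:
    """Count consecutive-fixation AOI transitions over all trials in view.

    A fixation with an empty AOI set maps to the no-AOI pseudo-label when
    ``include_no_aoi`` is set, otherwise pairs involving it are skipped
    (the empty fixation still advances the chain).  Overlapping hits fan
    out: ``{A,B} -> C`` adds one count to both A->C and B->C.
    """
    order = [a.aoi_id for a in dataset.effective_aois()]
    if include_no_aoi:
        order.append(NO_AOI_LABEL)
    index = {a: i for i, a in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=np.int64)

    for _, segs in dataset.trials():
        fixations = [s for s in segs if s.category == "fixation"]
        for prev, cur in zip(fixations, fixations[1:]):
            src = dataset.resolved_aoi_ids(prev) or (
                frozenset([NO_AOI_LABEL]) if include_no_aoi else frozenset()
            )
            dst = dataset.resolved_aoi_ids(cur) or (
                frozenset([NO_AOI_LABEL]) if include_no_aoi else frozenset()
            )
            for a in src:
                for b in dst:
                    if a == b and not include_self:
                        continue
                    counts[index[a], index[b]] += 1

    return TransitionMatrix(
        aoi_order=tuple(order), counts=counts, scope=scope or ViewFilter()
    )
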