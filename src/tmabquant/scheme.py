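"""Labeling schemes: which tag carries which condition/replicate in each run.

A multiplex experiment pools 4–5 differentially labeled samples per LC-MS run.
Because the tags have slightly different chemical properties, real studies
rotate the tag↔condition assignment between runs; :meth:`LabelingScheme.balanced`
builds such a rotation.  Every run must contain at least one reference-condition
channel, since all ratios are expressed relative to the within-run mean of the
reference channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import yaml

from .chemistry import TAG_NAMES, TAGS, TmabTag

__all__ = ["SchemeError", "ChannelAssignment", "LabelingScheme"]


class SchemeError(ValueError):
    """Invalid labeling scheme (duplicate tags, missing reference channel...)."""


@dataclass(frozen=True)
class ChannelAssignment:
    """One tag channel in one run."""

    run_id: str
    tag: str
    condition: str
    replicate: str


@dataclass
class LabelingScheme:
    """Per-run mapping ``tag -> (condition, replicate)`` plus the reference condition."""

    runs: Dict[str, Dict[str, Tuple[str, str]]]
    reference: str

    def __post_init__(self) -> None:
        if not self.runs:
            raise SchemeError("scheme contains no runs")
        for run_id, channels in self.runs.items():
            if not channels:
                raise SchemeError(f"run {run_id!r} has no channels")
            for tag in channels:
                if tag not in TAG_NAMES:
                    raise SchemeError(f"run {run_id!r}: unknown tag {tag!r}")
            if len(channels) > len(TAG_NAMES):
                raise SchemeError(f"run {run_id!r} assigns more channels than tags exist")
            conditions = [c for c, _ in channels.values()]
            if self.reference not in conditions:
                raise SchemeError(
                    f"run {run_id!r} lacks a {self.reference!r} (reference) channel"
                )
        reps = [(c, r) for channels in self.runs.values() for c, r in channels.values()]
        if len(set(reps)) != len(reps):
            raise SchemeError("a (condition, replicate) pair is assigned in more than one channel")

    # -- queries ---------------------------------------------------------

    @property
    def run_ids(self) -> List[str]:
        return list(self.runs)

    def tags_in_run(self, run_id: str) -> List[TmabTag]:
        return [TAGS[t] for t in self.runs[run_id]]

    def reference_tags(self, run_id: str) -> List[str]:
        return [t for t, (c, _) in self.runs[run_id].items() if c == self.reference]

    def conditions(self) -> List[str]:
        seen: List[str] = []
        for channels in self.runs.values():
            for cond, _ in channels.values():
                if cond not in seen:
                    seen.append(cond)
        return seen

    def channels(self) -> Iterator[ChannelAssignment]:
        for run_id, chans in self.runs.items():
            for tag, (cond, rep) in chans.items():
                yield ChannelAssignment(run_id, tag, cond, rep)

    # -- construction ----------------------------------------------------

    @classmethod
    def balanced(
        cls,
        conditions: Mapping[str, int],
        reference: str,
        tags_per_run: int = 5,
    ) -> "LabelingScheme":
        """Rotation scheme distributing replicates over 4–5-plex runs.

        ``conditions`` maps condition name to replicate count.  Replicates are
        interleaved across conditions (reference first) so every run carries at
        least one reference channel, and the tag assignment is rotated between
        runs so no condition always rides the same isotopologue.
        """
        if reference not in conditions:
            raise SchemeError(f"reference {reference!r} not among conditions")
        if not 2 <= tags_per_run <= len(TAG_NAMES):
            raise SchemeError(f"tags_per_run must be in [2, {len(TAG_NAMES)}]")
        order = [reference] + [c for c in conditions if c != reference]
        queues = {c: [f"{c}_r{i+1}" for i in range(conditions[c])] for c in order}
        stream: List[Tuple[str, str]] = []
        while any(queues.values()):
            for c in order:
                if queues[c]:
                    stream.append((c, queues[c].pop(0)))
        n_runs = -(-len(stream) // tags_per_run)
        runs: Dict[str, Dict[str, Tuple[str, str]]] = {}
        for i in range(n_runs):
            chunk = stream[i * tags_per_run : (i + 1) * tags_per_run]
            if not any(c == reference for c, _ in chunk):
                # steal the next reference replicate from an earlier run if the
                # tail chunk happens to contain none (rare, small designs)
                raise SchemeError("replicate layout left a run without a reference channel")
            tags = [TAG_NAMES[(j + i) % len(TAG_NAMES)] for j in range(len(chunk))]
            runs[f"run{i+1}"] = {t: cr for t, cr in zip(tags, chunk)}
        return cls(runs=runs, reference=reference)

    # -- (de)serialisation -----------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "reference": self.reference,
            "runs": {
                run: {tag: {"condition": c, "replicate": r} for tag, (c, r) in chans.items()}
                for run, chans in self.runs.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LabelingScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        runs = {
            run: {tag: (d["condition"], str(d["replicate"])) for tag, d in chans.items()}
            for run, chans in doc["runs"].items()
        }
        return cls(runs=runs, reference=doc["reference"])
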