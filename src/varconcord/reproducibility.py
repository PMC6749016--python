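"""Replicate and between-laboratory reproducibility of qualitative calls.

Reproducibility is assessed on *expected positives*: (sample, variant-or-
fusion key) events known to be present in plated reference samples.  Two
metrics are provided:

* between-lab accuracy — the fraction of expected positives detected
  identically (i.e. by both) in two laboratories' runs;
* replicate concordance — pooled pairwise agreement of replicate calls,
  either within plates (intra-plate) or across plates run with different
  reagent lots and operators (inter-plate).  A replicate pair agrees on an
  expected positive when both replicates call it or both miss it.

Both are qualitative: agreement requires identity of the canonical key,
never closeness of VAFs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .callset import CallSet, VariantKey
from .concordance import ProportionWithCI, proportion_with_ci


@dataclass(frozen=True)
class ReplicateEntry:
    """One physical well: a sample replicate on a plate."""

    sample_id: str
    replicate_index: int
    plate_id: str
    reagent_lot: str = ""
    lab_id: str = ""
    operator_id: str = ""

    @property
    def replicate_uid(self) -> str:
        """Identifier carried as the sample id of the replicate's calls."""
        return f"{self.sample_id}::{self.plate_id}::r{self.replicate_index}"


@dataclass
class ReplicateDesign:
    """A plated replicate layout plus the events each sample should yield."""

    entries: list = field(default_factory=list)
    expected_positive_calls: set = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            k = (e.sample_id, e.replicate_index, e.plate_id)
            if k in seen:
                raise ValueError(f"duplicate replicate entry {k}")
            seen.add(k)
        designed = {e.sample_id for e in self.entries}
        for sample_id, _key in self.expected_positive_calls:
            if sample_id not in designed:
                raise ValueError(
                    f"expected positive references undesigned sample {sample_id!r}"
                )

    def samples(self) -> set:
        return {e.sample_id for e in self.entries}

    def plates(self) -> set:
        return {e.plate_id for e in self.entries}


def triplicate_design(
    variant_samples: Iterable[str],
    fusion_samples: Iterable[str] = (),
    n_plates: int = 3,
    n_replicates: int = 3,
    expected_positive_calls: Optional[set] = None,
) -> ReplicateDesign:
    """The standard layout: each positive sample plated in ``n_replicates``
    per plate across ``n_plates`` plates, one reagent lot and operator per
    plate."""
    entries = []
    for sample in list(variant_samples) + list(fusion_samples):
        for p in range(1, n_plates + 1):
            for r in range(1, n_replicates + 1):
                entries.append(
                    ReplicateEntry(
                        sample_id=sample,
                        replicate_index=r,
                        plate_id=f"plate{p}",
                        reagent_lot=f"lot{p}",
                        lab_id="lab1",
                        operator_id=f"op{p}",
                    )
                )
    return ReplicateDesign(
        entries=entries, expected_positive_calls=expected_positive_calls or set()
    )


def _detected_events(calls: CallSet) -> set:
    return calls.variant_events() | calls.fusion_events()


def _norm_key(key):
    return key if isinstance(key, (VariantKey, str)) else str(key)


def between_lab_accuracy(
    calls_lab1: CallSet,
    calls_lab2: CallSet,
    expected: set,
    conf_level: float = 0.95,
    level: str = "event",
) -> ProportionWithCI:
    """Fraction of expected positives detected identically in both labs.

    ``level="event"`` counts individual (sample, key) events;
    ``level="sample"`` counts a sample as accurate only when all its
    expected positives were detected in both labs.
    """
    expected = {(s, _norm_key(k)) for (s, k) in expected}
    if not expected:
        raise ValueError("between_lab_accuracy requires a non-empty expected set")
    ev1, ev2 = _detected_events(calls_lab1), _detected_events(calls_lab2)
    hit = {e for e in expected if e in ev1 and e in ev2}
    if level == "event":
        return proportion_with_ci(len(hit), len(expected), conf_level)
    if level == "sample":
        samples = {s for (s, _k) in expected}
        good = sum(
            1
            for s in samples
            if all(e in hit for e in expected if e[0] == s)
        )
        return proportion_with_ci(good, len(samples), conf_level)
    raise ValueError(f"unknown level {level!r}")


def replicate_concordance(
    calls: CallSet,
    design: ReplicateDesign,
    mode: str,
    conf_level: float = 0.95,
) -> ProportionWithCI:
    """Pooled pairwise replicate agreement on expected positives.

    ``calls`` must carry :attr:`ReplicateEntry.replicate_uid` as its sample
    ids.  ``mode="intra_plate"`` pools pairs of replicates on the same
    plate; ``mode="inter_plate"`` pools pairs on different plates.
    """
    if mode not in ("intra_plate", "inter_plate"):
        raise ValueError(f"unknown mode {mode!r}")
    detected = _detected_events(calls)
    expected = {(s, _norm_key(k)) for (s, k) in design.expected_positive_calls}
    if not expected:
        raise ValueError("design carries no expected positive calls")

    agree = total = 0
    for sample_id, key in sorted(expected, key=lambda e: (e[0], str(e[1]))):
        entries = [e for e in design.entries if e.sample_id == sample_id]
        calls_by_entry = {
            e: ((e.replicate_uid, key) in detected) for e in entries
        }
        for e1, e2 in itertools.combinations(entries, 2):
            same_plate = e1.plate_id == e2.plate_id
            if (mode == "intra_plate") != same_plate:
                continue
            total += 1
            if calls_by_entry[e1] == calls_by_entry[e2]:
                agree += 1
    if total == 0:
        raise ValueError(f"no eligible replicate pairs for mode {mode!r}")
    return proportion_with_ci(agree, total, conf_level)
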