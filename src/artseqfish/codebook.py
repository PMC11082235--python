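"""Colour-round barcodes and the codebook that maps targets onto them.

A target's barcode is the set of (hybridisation round, colour channel) pairs
in which its readout probes fluoresce.  With four readout flanks on the
bridge probe a target can light up in at most four rounds, once per round.
The default channel set is (ATTO488, TAMRA, CY5) — green, red, far-red.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

SPECIES_CLASSES = ("mRNA", "protein", "phosphoprotein")

MAX_SLOTS_PER_BARCODE = 4  # one per bridge-probe readout flank


class CodebookError(ValueError):
    pass


@dataclass(frozen=True)
class ChannelSet:
    """Ordered fluorescence channel labels."""

    labels: tuple[str, ...] = ("ATTO488", "TAMRA", "CY5")

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise CodebookError("ChannelSet needs at least one channel")
        if len(set(self.labels)) != len(self.labels):
            raise CodebookError("channel labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        if label not in self.labels:
            raise CodebookError(f"unknown channel {label!r}; known: {list(self.labels)}")
        return self.labels.index(label)


@dataclass(frozen=True)
class Barcode:
    """A set of (round, channel) presences, at most one channel per round."""

    slots: frozenset[tuple[int, str]]

    def __post_init__(self) -> None:
        k = len(self.slots)
        if not 1 <= k <= MAX_SLOTS_PER_BARCODE:
            raise CodebookError(f"barcode must use 1..{MAX_SLOTS_PER_BARCODE} slots, got {k}")
        rounds = [r for r, _ in self.slots]
        if len(set(rounds)) != len(rounds):
            raise CodebookError("at most one channel per round per target")
        for r, _c in self.slots:
            if r < 0:
                raise CodebookError("round indices are 0-based and non-negative")

    @classmethod
    def of(cls, *slots: tuple[int, str]) -> "Barcode":
        return cls(frozenset(slots))

    def __len__(self) -> int:
        return len(self.slots)

    def __contains__(self, slot: tuple[int, str]) -> bool:
        return slot in self.slots

    def set_difference(self, other: "Barcode") -> int:
        """Symmetric set difference between two barcodes."""
        return len(self.slots ^ other.slots)


@dataclass(frozen=True)
class CodebookEntry:
    target_id: str
    species_class: str
    functional_class: str
    barcode: Barcode


@dataclass(frozen=True)
class Codebook:
    entries: tuple[CodebookEntry, ...]
    n_rounds: int
    channels: ChannelSet = field(default_factory=ChannelSet)

    def __post_init__(self) -> None:
        ids = [e.target_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise CodebookError("target_ids must be unique")
        codes = [e.barcode.slots for e in self.entries]
        if len(set(codes)) != len(codes):
            raise CodebookError("barcodes must be pairwise distinct")
        for e in self.entries:
            for r, c in e.barcode.slots:
                if r >= self.n_rounds:
                    raise CodebookError(
                        f"target {e.target_id!r} uses round {r} >= n_rounds={self.n_rounds}")
                self.channels.index(c)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_ids(self) -> list[str]:
        return [e.target_id for e in self.entries]

    def barcode_of(self, target_id: str) -> Barcode:
        for e in self.entries:
            if e.target_id == target_id:
                return e.barcode
        raise CodebookError(f"unknown target {target_id!r}")

    def entry_of(self, target_id: str) -> CodebookEntry:
        for e in self.entries:
            if e.target_id == target_id:
                return e
        raise CodebookError(f"unknown target {target_id!r}")


def capacity(n_rounds: int, n_channels: int, max_slots: int) -> int:
    """Number of distinct barcodes with 1..max_slots slots.

    A barcode chooses j rounds out of ``n_rounds`` and one of ``n_channels``
    colours in each, so the total is sum_j C(n_rounds, j) * n_channels**j.
    """
    if n_rounds <= 0 or n_channels <= 0 or max_slots <= 0:
        raise CodebookError("all arguments must be positive")
    if max_slots > n_rounds:
        raise CodebookError(f"max_slots={max_slots} exceeds n_rounds={n_rounds}")
    return sum(math.comb(n_rounds, j) * n_channels**j for j in range(1, max_slots + 1))


def _enumerate_barcodes(n_rounds: int, channels: ChannelSet,
                        min_slots: int, max_slots: int) -> list[Barcode]:
    out = []
    for j in range(min_slots, max_slots + 1):
        for rounds in itertools.combinations(range(n_rounds), j):
            for cols in itertools.product(channels.labels, repeat=j):
                out.append(Barcode(frozenset(zip(rounds, cols))))
    return out


def generate_codebook(
    n_targets: int,
    n_rounds: int,
    channels: ChannelSet = ChannelSet(),
    max_slots: int = MAX_SLOTS_PER_BARCODE,
    min_set_difference: int = 2,
    seed: int = 0,
    min_slots: int = 1,
    species_classes: Iterable[str] = SPECIES_CLASSES,
    functional_classes: Iterable[str] = ("unassigned",),
) -> Codebook:
    """Draw a reproducible codebook of ``n_targets`` distinct barcodes.

    Barcodes are chosen greedily from a seeded random permutation of the
    full barcode space, keeping a candidate only when its symmetric set
    difference to every kept barcode is at least ``min_set_difference``.
    A margin of 2 allows one-dropout disambiguation during decoding.
    Species / functional class labels cycle through the provided lists.
    """
    max_slots = min(max_slots, MAX_SLOTS_PER_BARCODE)
    cap = capacity(n_rounds, len(channels), max_slots)
    if cap < n_targets:
        raise CodebookError(
            f"requested {n_targets} targets but only {cap} barcodes exist for "
            f"{n_rounds} rounds x {len(channels)} channels with <= {max_slots} slots")
    pool = _enumerate_barcodes(n_rounds, channels, min_slots, max_slots)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    kept: list[Barcode] = []
    for idx in order:
        cand = pool[idx]
        if all(cand.set_difference(k) >= min_set_difference for k in kept):
            kept.append(cand)
            if len(kept) == n_targets:
                break
    if len(kept) < n_targets:
        raise CodebookError(
            f"could not find {n_targets} barcodes with pairwise set difference "
            f">= {min_set_difference} (found {len(kept)} of {cap} candidates)")
    species = list(species_classes)
    func = list(functional_classes)
    entries = tuple(
        CodebookEntry(
            target_id=f"target_{i:03d}",
            species_class=species[i % len(species)],
            functional_class=func[i % len(func)],
            barcode=bc,
        )
        for i, bc in enumerate(kept)
    )
    return Codebook(entries=entries, n_rounds=n_rounds, channels=channels)


@dataclass(frozen=True)
class CodebookReport:
    valid: bool
    duplicates: tuple[tuple[str, str], ...]
    out_of_range: tuple[str, ...]
    per_round_channel_load: Mapping[tuple[int, str], int]
    min_pairwise_set_difference: int | None


def validate_codebook(cb: Codebook) -> CodebookReport:
    """Report duplicate barcodes, out-of-range rounds and optical load.

    ``per_round_channel_load`` counts, per (round, channel), how many targets
    fluoresce there — the quantity to budget against optical crowding.
    """
    dups = []
    for a, b in itertools.combinations(cb.entries, 2):
        if a.barcode.slots == b.barcode.slots:
            dups.append((a.target_id, b.target_id))
    oor = tuple(e.target_id for e in cb.entries
                if any(r >= cb.n_rounds for r, _ in e.barcode.slots))
    load: dict[tuple[int, str], int] = {}
    for e in cb.entries:
        for slot in e.barcode.slots:
            load[slot] = load.get(slot, 0) + 1
    min_diff = None
    if len(cb.entries) > 1:
        min_diff = min(a.barcode.set_difference(b.barcode)
                       for a, b in itertools.combinations(cb.entries, 2))
    return CodebookReport(valid=not dups and not oor, duplicates=tuple(dups),
                          out_of_range=oor, per_round_channel_load=load,
                          min_pairwise_set_difference=min_diff)


# ---------------------------------------------------------------------------
# Serialization: CSV with one column per round, and a JSON mirror.

_ABSENT = "-"


def write_codebook(cb: Codebook, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "n_rounds": cb.n_rounds,
            "channels": list(cb.channels.labels),
            "entries": [
                {
                    "target_id": e.target_id,
                    "species_class": e.species_class,
                    "functional_class": e.functional_class,
                    "barcode": sorted([r, c] for r, c in e.barcode.slots),
                }
                for e in cb.entries
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["target_id", "species_class", "functional_class"]
                   + [f"round_{r}" for r in range(cb.n_rounds)])
        for e in cb.entries:
            by_round = dict(e.barcode.slots)
            w.writerow([e.target_id, e.species_class, e.functional_class]
                       + [by_round.get(r, _ABSENT) for r in range(cb.n_rounds)])


def read_codebook(path: str | Path, channels: ChannelSet = ChannelSet()) -> Codebook:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        channels = ChannelSet(tuple(payload["channels"]))
        entries = tuple(
            CodebookEntry(
                target_id=e["target_id"],
                species_class=e["species_class"],
                functional_class=e["functional_class"],
                barcode=Barcode(frozenset((int(r), c) for r, c in e["barcode"])),
            )
            for e in payload["entries"]
        )
        if not entries:
            raise CodebookError(f"no entries in {path}")
        return Codebook(entries=entries, n_rounds=int(payload["n_rounds"]),
                        channels=channels)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise CodebookError(f"no entries in {path}")
    header = rows[0]
    round_cols = [i for i, h in enumerate(header) if h.startswith("round_")]
    if header[:3] != ["target_id", "species_class", "functional_class"] or not round_cols:
        raise CodebookError(f"malformed codebook header in {path}: {header}")
    n_rounds = len(round_cols)
    entries = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise CodebookError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        slots = set()
        for r, i in enumerate(round_cols):
            val = row[i].strip()
            if val == _ABSENT or val == "":
                continue
            if val not in channels.labels:
                raise CodebookError(
                    f"{path}:{lineno}: unknown channel {val!r}; known: {list(channels.labels)}")
            slots.add((r, val))
        try:
            barcode = Barcode(frozenset(slots))
        except CodebookError as exc:
            raise CodebookError(f"{path}:{lineno}: {exc}") from exc
        entries.append(CodebookEntry(row[0], row[1], row[2], barcode))
    return Codebook(entries=tuple(entries), n_rounds=n_rounds, channels=channels)
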