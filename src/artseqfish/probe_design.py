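"""In-silico design of the padlock-probe / bridge-probe oligonucleotide set.

Each mRNA target is detected by an 84-nt padlock probe (PLP) whose two 18-nt
arms jointly hybridise a 36-nt window of the transcript; (phospho-)proteins
are detected through a 46-nt antibody-conjugated oligo (10-nt poly-A linker +
36-nt unique sequence) that serves as the PLP landing site instead.  The
circularised PLP is amplified by rolling-circle amplification; a 108-nt
bridge probe (BrP) hybridises the amplicon through a shared 28-nt unique
sequence and presents four 18-nt readout-probe flanks separated by "AA"
spacers.  All probes must keep their GC content within 45-65% and any
stretch complementary to an off-target transcript below 13 nt.

The 28-nt unique sequences, 20-nt RCA primer and 18-nt readout sequences are
user-supplied (they come from an orthogonal-sequence generator outside this
package); this module assembles and validates the full-length probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class ProbeDesignError(ValueError):
    """Base error for invalid probe components or failed design constraints."""


class NoValidRegionError(ProbeDesignError):
    """No window of the transcript satisfies the arm GC constraints."""


def _check_seq(seq: str, what: str = "sequence") -> str:
    if not isinstance(seq, str) or len(seq) == 0:
        raise ProbeDesignError(f"{what} must be a non-empty string")
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ProbeDesignError(f"{what} contains non-ACGT symbols: {bad}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return _check_seq(seq).translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC content of ``seq`` as a percentage in [0, 100]."""
    _check_seq(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (e.g. one transcript from a FASTA file)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_seq(self.seq, f"sequence of record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProbeArchitecture:
    """Lengths and filters of the probe chemistry.

    Defaults give an 84-nt padlock probe (2*18 + 28 + 20), a 108-nt bridge
    probe (4*18 + 28 + 4*2) and a 46-nt antibody oligo (10 + 36).
    """

    arm_len: int = 18
    unique_len: int = 28
    rca_primer_len: int = 20
    readout_len: int = 18
    ab_linker_len: int = 10
    ab_unique_len: int = 36
    spacer: str = "AA"
    gc_min: float = 45.0
    gc_max: float = 65.0
    max_offtarget_match: int = 12

    def __post_init__(self) -> None:
        for name in ("arm_len", "unique_len", "rca_primer_len", "readout_len",
                     "ab_linker_len", "ab_unique_len", "max_offtarget_match"):
            if int(getattr(self, name)) <= 0:
                raise ProbeDesignError(f"{name} must be a positive integer")
        if not self.gc_min < self.gc_max:
            raise ProbeDesignError("gc_min must be < gc_max")
        _check_seq(self.spacer, "spacer")

    @property
    def target_len(self) -> int:
        """Length of the transcript window covered by the two PLP arms."""
        return 2 * self.arm_len

    @property
    def plp_len(self) -> int:
        return 2 * self.arm_len + self.unique_len + self.rca_primer_len

    @property
    def brp_len(self) -> int:
        return 4 * self.readout_len + self.unique_len + 4 * len(self.spacer)

    @property
    def ab_oligo_len(self) -> int:
        return self.ab_linker_len + self.ab_unique_len


@dataclass(frozen=True)
class PadlockProbe:
    """84-nt padlock probe: [18-nt 5' arm][28-nt unique][20-nt RCA primer][18-nt 3' arm]."""

    target_id: str
    arm5: str
    unique28: str
    rca_primer: str
    arm3: str

    @property
    def full_seq(self) -> str:
        return self.arm5 + self.unique28 + self.rca_primer + self.arm3


@dataclass(frozen=True)
class BridgeProbe:
    """108-nt bridge probe: readout1-AA-readout2-AA-unique28-AA-readout3-AA-readout4."""

    target_id: str
    readouts: tuple[str, str, str, str]
    unique28: str
    spacer: str = "AA"

    @property
    def full_seq(self) -> str:
        r1, r2, r3, r4 = self.readouts
        s = self.spacer
        return r1 + s + r2 + s + self.unique28 + s + r3 + s + r4


@dataclass(frozen=True)
class AntibodyOligo:
    """46-nt antibody-conjugated oligo: 10-nt poly-A linker + 36-nt unique sequence."""

    antibody_id: str
    unique36: str
    linker: str = "A" * 10

    @property
    def full_seq(self) -> str:
        return self.linker + self.unique36


def _require_len(seq: str, expected: int, what: str) -> str:
    _check_seq(seq, what)
    if len(seq) != expected:
        raise ProbeDesignError(f"{what}: expected length {expected}, got {len(seq)}")
    return seq


def passes_gc_filter(seq: str, arch: ProbeArchitecture = ProbeArchitecture()) -> bool:
    """True iff GC content lies within [gc_min, gc_max] (bounds inclusive)."""
    gc = gc_content(seq)
    return arch.gc_min <= gc <= arch.gc_max


def select_target_region(
    mrna: SequenceRecord, arch: ProbeArchitecture = ProbeArchitecture()
) -> tuple[str, int]:
    """Select the leftmost 36-nt transcript window usable as a PLP target.

    Both 18-nt halves of the window (the future arm binding sites) must pass
    the GC filter independently.  Returns ``(window, offset)`` with a 0-based
    offset; raises :class:`NoValidRegionError` if no window qualifies.
    """
    n, w = len(mrna.seq), arch.target_len
    if n < w:
        raise NoValidRegionError(
            f"transcript {mrna.id!r} is shorter ({n} nt) than the {w}-nt target window"
        )
    half = arch.arm_len
    for off in range(n - w + 1):
        window = mrna.seq[off : off + w]
        if passes_gc_filter(window[:half], arch) and passes_gc_filter(window[half:], arch):
            return window, off
    raise NoValidRegionError(
        f"no valid {w}-nt target region in transcript {mrna.id!r}: "
        f"no window has both arm halves with GC in [{arch.gc_min}, {arch.gc_max}]%"
    )


def assemble_plp(
    target36: str,
    unique28: str,
    rca_primer: str,
    arch: ProbeArchitecture = ProbeArchitecture(),
    target_id: str = "",
) -> PadlockProbe:
    """Assemble a padlock probe against a 36-nt target window.

    The 5' arm reverse-complements the 3' half of the target and the 3' arm
    the 5' half, so that after hybridisation the ligation junction (3' end of
    the 3' arm meeting the 5' end of the 5' arm) sits mid-target.
    """
    _require_len(target36, arch.target_len, "target36")
    _require_len(unique28, arch.unique_len, "unique28")
    _require_len(rca_primer, arch.rca_primer_len, "rca_primer")
    arm5 = reverse_complement(target36[arch.arm_len :])
    arm3 = reverse_complement(target36[: arch.arm_len])
    return PadlockProbe(target_id=target_id, arm5=arm5, unique28=unique28,
                        rca_primer=rca_primer, arm3=arm3)


def assemble_brp(
    readouts: Sequence[str],
    unique28: str,
    arch: ProbeArchitecture = ProbeArchitecture(),
    target_id: str = "",
) -> BridgeProbe:
    """Assemble a bridge probe from four 18-nt readout flanks and the paired unique28."""
    if len(readouts) != 4:
        raise ProbeDesignError(f"expected exactly 4 readout sequences, got {len(readouts)}")
    for i, r in enumerate(readouts):
        _require_len(r, arch.readout_len, f"readout {i + 1}")
    _require_len(unique28, arch.unique_len, "unique28")
    return BridgeProbe(target_id=target_id, readouts=tuple(readouts),
                       unique28=unique28, spacer=arch.spacer)


def assemble_ab_oligo(
    unique36: str,
    arch: ProbeArchitecture = ProbeArchitecture(),
    antibody_id: str = "",
) -> AntibodyOligo:
    """Assemble a 46-nt antibody oligo: poly-A linker + 36-nt unique sequence."""
    _require_len(unique36, arch.ab_unique_len, "unique36")
    return AntibodyOligo(antibody_id=antibody_id, unique36=unique36,
                         linker="A" * arch.ab_linker_len)


@dataclass(frozen=True)
class CrossHybResult:
    passed: bool
    longest_match: int
    transcript_id: str | None = None


def _longest_shared_substring(a: str, b: str) -> int:
    """Length of the longest substring shared by ``a`` and ``b``.

    Binary search over the length; at each length the candidate substrings of
    the shorter string are hashed into a set and scanned against the longer.
    """
    if not a or not b:
        return 0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    lo, hi, best = 1, len(short), 0

    def shared(k: int) -> bool:
        subs = {short[i : i + k] for i in range(len(short) - k + 1)}
        return any(long_[i : i + k] in subs for i in range(len(long_) - k + 1))

    while lo <= hi:
        mid = (lo + hi) // 2
        if shared(mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def cross_hybridization_check(
    probe_seq: str,
    transcriptome: Iterable[SequenceRecord],
    arch: ProbeArchitecture = ProbeArchitecture(),
) -> CrossHybResult:
    """Check a probe for off-target complementarity against a transcriptome.

    Finds the longest exact substring of ``probe_seq`` whose reverse
    complement occurs in any off-target transcript (equivalently, the longest
    substring shared by the reverse complement of the probe and a
    transcript).  The probe passes iff that length is at most
    ``arch.max_offtarget_match`` (i.e. strictly below 13 nt by default).
    """
    _check_seq(probe_seq, "probe_seq")
    rc = reverse_complement(probe_seq)
    best, best_id = 0, None
    empty = True
    for rec in transcriptome:
        empty = False
        m = _longest_shared_substring(rc, rec.seq)
        if m > best:
            best, best_id = m, rec.id
    if empty:
        warnings.warn("empty transcriptome: cross-hybridization check is vacuous",
                      stacklevel=2)
        return CrossHybResult(passed=True, longest_match=0)
    return CrossHybResult(passed=best <= arch.max_offtarget_match,
                          longest_match=best, transcript_id=best_id)


# ---------------------------------------------------------------------------
# FASTA / manifest I/O


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects (uppercased)."""
    from Bio import SeqIO

    records = [SequenceRecord(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ProbeDesignError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ProbeDesignError(f"duplicate record ids in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
                str(path), "fasta")


def design_probe_set(
    mrnas: Sequence[SequenceRecord],
    unique28s: Sequence[str],
    rca_primer: str,
    readout_sets: Sequence[Sequence[str]],
    arch: ProbeArchitecture = ProbeArchitecture(),
    transcriptome: Sequence[SequenceRecord] | None = None,
) -> pd.DataFrame:
    """Design the full PLP + BrP pair for each transcript.

    ``unique28s`` and ``readout_sets`` are user-supplied orthogonal sequences,
    one entry per transcript.  Returns a manifest table with component
    sequences, full-length probes, GC content and (optionally) the off-target
    check against ``transcriptome`` excluding the probe's own transcript.
    """
    if not (len(mrnas) == len(unique28s) == len(readout_sets)):
        raise ProbeDesignError("mrnas, unique28s and readout_sets must have equal length")
    rows = []
    for mrna, u28, readouts in zip(mrnas, unique28s, readout_sets):
        target36, offset = select_target_region(mrna, arch)
        plp = assemble_plp(target36, u28, rca_primer, arch, target_id=mrna.id)
        brp = assemble_brp(readouts, u28, arch, target_id=mrna.id)
        row = {
            "target_id": mrna.id,
            "target36": target36,
            "target_offset": offset,
            "arm5": plp.arm5,
            "unique28": u28,
            "rca_primer": rca_primer,
            "arm3": plp.arm3,
            "plp_full_seq": plp.full_seq,
            "brp_full_seq": brp.full_seq,
            "plp_gc": gc_content(plp.full_seq),
            "brp_gc": gc_content(brp.full_seq),
        }
        if transcriptome is not None:
            others = [t for t in transcriptome if t.id != mrna.id]
            chk = cross_hybridization_check(plp.full_seq, others, arch) if others \
                else CrossHybResult(True, 0)
            row["offtarget_longest_match"] = chk.longest_match
            row["offtarget_pass"] = chk.passed
        rows.append(row)
    return pd.DataFrame(rows)
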