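"""Per-position 5'/3' end-count profiles from RiboMethSeq alignments.

The cleavage signal lives on phosphodiester bonds: the combined count at
nucleotide ``i`` (1-based) aggregates the two read ends reporting the
bond 3' of ``i`` — reads starting at ``i + 1`` (a 5'-end produced by
cleavage of that bond) plus reads ending at ``i`` (the matching 3'-end).
3'-ends are counted only for short reads, because the 3' position of
long reads is set by the sequencing read length rather than by the
cleavage site.

External coordinates (TSV, annotations, CLI) are 1-based throughout;
internal numpy arrays are 0-based with index ``i`` holding position
``i + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Reads at or above this aligned length contribute no 3'-end counts.
DEFAULT_MAX_LEN_3P = 40


class ProfileParseError(ValueError):
    """Raised when a profile TSV violates the format contract."""


@dataclass
class EndCountProfile:
    """Per-position cleavage end counts for one reference sequence.

    Attributes
    ----------
    ref_name : str
        Reference sequence identifier.
    count5 : numpy.ndarray
        Reads whose leftmost aligned base maps at each position.
    count3 : numpy.ndarray
        Reads whose rightmost aligned base maps at each position, after
        the short-read length filter.
    n_reads_counted, n_reads_skipped : int
        Accounting tallies for the records that produced the profile.
    """

    ref_name: str
    count5: np.ndarray
    count3: np.ndarray
    n_reads_counted: int = 0
    n_reads_skipped: int = 0

    def __post_init__(self) -> None:
        self.count5 = np.asarray(self.count5, dtype=np.int64)
        self.count3 = np.asarray(self.count3, dtype=np.int64)
        if self.count5.shape != self.count3.shape or self.count5.ndim != 1:
            raise ValueError("count5 and count3 must be 1-D arrays of equal length")
        if len(self.count5) == 0:
            raise ValueError("profile length must be positive")
        if (self.count5 < 0).any() or (self.count3 < 0).any():
            raise ValueError("end counts must be non-negative")

    @property
    def length(self) -> int:
        return len(self.count5)

    @property
    def countN(self) -> np.ndarray:
        """Combined count n_i = count5[i+1] + count3[i] per nucleotide.

        At the last position only the 3'-end track exists (there is no
        read start beyond the reference); the partial sum is used there.
        """
        n = self.count3.copy()
        n[:-1] += self.count5[1:]
        return n

    def copy(self) -> "EndCountProfile":
        return replace(self, count5=self.count5.copy(), count3=self.count3.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndCountProfile):
            return NotImplemented
        return (
            self.ref_name == other.ref_name
            and np.array_equal(self.count5, other.count5)
            and np.array_equal(self.count3, other.count3)
        )


def _open_alignments(alignments) -> pysam.AlignmentFile:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return pysam.AlignmentFile(str(alignments), check_sq=False)


def count_ends(
    alignments,
    ref: str | None = None,
    ref_length: int | None = None,
    max_len_3p: int = DEFAULT_MAX_LEN_3P,
    min_mapq: int = 0,
) -> EndCountProfile:
    """Tally read 5'- and 3'-ends per reference position.

    Parameters
    ----------
    alignments : path or pysam.AlignmentFile
        SAM/BAM records, read sequentially (no index required).
    ref : str, optional
        Reference to count against; may be omitted when the header
        declares exactly one reference.
    ref_length : int, optional
        Overrides the header length (rarely needed).
    max_len_3p : int
        3'-ends are counted only for reads whose aligned query length is
        strictly below this threshold (default 40 nt); longer reads have
        sequencer-determined 3' positions that carry no cleavage signal.
    min_mapq : int
        Minimum mapping quality; 0 (default) disables the filter, since
        multi-mapping within rRNA repeats is resolved upstream by the
        aligner's reporting.

    Notes
    -----
    Unmapped, secondary, supplementary and reverse-strand records are
    skipped and tallied, never counted: the libraries are sense-stranded
    and antisense ends do not report bond cleavage. Duplicates are kept —
    fragmentation is random, so identical ends are signal.
    """
    if max_len_3p <= 0:
        raise ValueError("max_len_3p must be positive")
    af = _open_alignments(alignments)
    refs = list(af.references)
    if ref is None:
        if len(refs) != 1:
            raise ValueError(
                f"alignment header declares {len(refs)} references; pass ref= explicitly"
            )
        ref = refs[0]
    elif ref not in refs:
        raise ValueError(f"reference {ref!r} absent from alignment header")
    length = ref_length if ref_length is not None else af.get_reference_length(ref)

    count5 = np.zeros(length, dtype=np.int64)
    count3 = np.zeros(length, dtype=np.int64)
    n_counted = 0
    n_skipped = 0
    n_reverse = 0
    n_seen = 0
    for rec in af.fetch(until_eof=True):
        n_seen += 1
        if (
            rec.is_unmapped
            or rec.is_secondary
            or rec.is_supplementary
            or rec.reference_name != ref
            or rec.mapping_quality < min_mapq
        ):
            n_skipped += 1
            continue
        if rec.is_reverse:
            n_reverse += 1
            n_skipped += 1
            continue
        start = rec.reference_start  # 0-based leftmost
        end = rec.reference_end - 1  # 0-based rightmost
        count5[start] += 1
        # aligned query length excludes soft-clips: trimming happened
        # upstream and clipped bases must not shift the length filter
        if rec.query_alignment_length < max_len_3p:
            count3[end] += 1
        n_counted += 1
    if n_reverse > 0.1 * max(n_seen, 1):
        logger.warning(
            "%d/%d records were reverse-strand and skipped", n_reverse, n_seen
        )
    if n_counted == 0:
        raise ValueError("no counted reads")
    return EndCountProfile(
        ref_name=ref,
        count5=count5,
        count3=count3,
        n_reads_counted=n_counted,
        n_reads_skipped=n_skipped,
    )


PROFILE_HEADER = "#ref\tpos\tcount5\tcount3\tcountN"


def save_profile(profiles: EndCountProfile | Iterable[EndCountProfile], path) -> None:
    """Write one or more profiles to a TSV (1-based positions, ascending)."""
    if isinstance(profiles, EndCountProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        fh.write(PROFILE_HEADER + "\n")
        for prof in profiles:
            countn = prof.countN
            for i in range(prof.length):
                fh.write(
                    f"{prof.ref_name}\t{i + 1}\t{prof.count5[i]}"
                    f"\t{prof.count3[i]}\t{countn[i]}\n"
                )


def load_profiles(path) -> dict[str, EndCountProfile]:
    """Parse a profile TSV into one :class:`EndCountProfile` per reference."""
    per_ref: dict[str, dict[str, list[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ProfileParseError(
                    f"{path}: line {lineno}: expected >=4 tab-separated columns"
                )
            ref = fields[0]
            try:
                pos, c5, c3 = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ProfileParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if c5 < 0 or c3 < 0:
                raise ProfileParseError(
                    f"{path}: line {lineno}: negative count"
                )
            rec = per_ref.setdefault(ref, {"pos": [], "c5": [], "c3": []})
            expected = len(rec["pos"]) + 1
            if pos != expected:
                raise ProfileParseError(
                    f"{path}: line {lineno}: non-contiguous position {pos} "
                    f"for {ref} (expected {expected})"
                )
            rec["pos"].append(pos)
            rec["c5"].append(c5)
            rec["c3"].append(c3)
    if not per_ref:
        raise ProfileParseError(f"{path}: no profile rows found")
    return {
        ref: EndCountProfile(
            ref_name=ref,
            count5=np.array(rec["c5"], dtype=np.int64),
            count3=np.array(rec["c3"], dtype=np.int64),
            n_reads_counted=int(np.sum(rec["c5"])),
        )
        for ref, rec in per_ref.items()
    }


def load_profile(path, ref: str | None = None) -> EndCountProfile:
    """Load a single profile, optionally selecting a reference by name."""
    profiles = load_profiles(path)
    if ref is not None:
        if ref not in profiles:
            raise KeyError(f"reference {ref!r} not present in {path}")
        return profiles[ref]
    if len(profiles) != 1:
        raise ValueError(
            f"{path} holds {len(profiles)} references; pass ref= to select one"
        )
    return next(iter(profiles.values()))


def subsample_profile(
    profile: EndCountProfile, fraction: float, seed: int
) -> EndCountProfile:
    """Binomially thin every count with retention probability ``fraction``.

    Emulates sequencing the same library to a lower depth: each counted
    end survives independently with probability ``fraction``, so the
    expectation of every count is ``fraction`` times the original.
    ``fraction == 1`` returns an identical copy.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return profile.copy()
    rng = np.random.default_rng(seed)
    count5 = rng.binomial(profile.count5, fraction)
    count3 = rng.binomial(profile.count3, fraction)
    return EndCountProfile(
        ref_name=profile.ref_name,
        count5=count5,
        count3=count3,
        n_reads_counted=int(count5.sum()),
        n_reads_skipped=profile.n_reads_skipped,
    )


def uncovered_positions(profile: EndCountProfile) -> np.ndarray:
    """1-based positions whose combined end count is zero.

    These are the positions where no cleavage fragment end was observed,
    reported when assessing whether sequencing depth suffices.
    """
    return np.flatnonzero(profile.countN == 0) + 1
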