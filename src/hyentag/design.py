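"""Orthogonal DNA barcode design and oligo assembly.

Each tag bit carries a unique 20-nt barcode domain ``Si`` drawn from a
three-letter alphabet {A, C, T} (no G, to suppress secondary structure), with
composition and homopolymer-run filters, a hairpin-stem filter, and two
pairwise orthogonality screens: a longest-shared-substring cap (checked in
sense and reverse-complement orientation) and a Smith-Waterman local-alignment
score cap.  Candidates are accepted greedily in generation order until the
requested library size is reached.

From an accepted library, :func:`build_oligos` assembles the five strands
that embody one bit:

* tag strand      ``<T* U* Si*>`` — the strand mixed into a tag; single-stranded = bit 1
* blocker strand  ``<U T>``       — universal across bits; bound to the tag strand = bit 0
* probe strand    ``<X Si U T>``  — fluorophore-arm strand of the paper-bound reporter
* anchor strand   ``<U* Si*>`` + 30-nt poly-T tail — binds the probe to nitrocellulose
* fluorophore strand ``<F X*>``   — displaced (and washed away) when a matching
  bit-1 strand invades the reporter

``F`` marks the dye position; the dye is a chemical moiety, not nucleotides,
so its sequence defaults to empty.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

try:
    from Bio.Align import PairwiseAligner
except ImportError:  # pragma: no cover
    PairwiseAligner = None

__all__ = [
    "DesignParams",
    "BarcodeLibrary",
    "OligoSet",
    "revcomp",
    "generate_candidates",
    "passes_composition",
    "passes_structure",
    "longest_hairpin_stem",
    "max_shared_substring",
    "local_align_screen",
    "build_library",
    "build_oligos",
    "generate_decoys",
    "write_fasta",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignParams:
    """Filter thresholds and generation settings for barcode design."""

    length: int = 20
    alphabet: tuple[str, ...] = ("A", "C", "T")
    c_content_range: tuple[float, float] = (0.30, 0.70)
    max_run_AT: int = 4
    max_run_C: int = 3
    max_shared_substring: int = 10
    hairpin_stem_max: int = 5
    min_loop: int = 3
    local_align_score_max: int = 12
    candidate_count: int = 10_000
    rng_seed: int = 0
    structure_hook: Callable[[str], bool] | None = field(
        default=None, compare=False
    )  # optional external predictor: seq -> passes?

    def __post_init__(self):
        lo, hi = self.c_content_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("c_content_range must satisfy 0 <= low <= high <= 1")
        if self.max_run_AT < 1 or self.max_run_C < 1:
            raise ValueError("run limits must be >= 1")
        if self.length < self.max_shared_substring:
            raise ValueError("length must be >= max_shared_substring")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet needs at least 2 distinct symbols")
        if not set(self.alphabet) <= set("ACGT"):
            raise ValueError("alphabet symbols must be DNA bases")


# Default shared-domain lengths: 6-nt toehold, 15-nt stabilizer, 15-nt
# fluorophore arm.  The toehold must be short enough to exchange reversibly,
# the stabilizer long enough to hold bit-0 duplexes at room temperature.
_SHARED_LENGTHS = {"T": 6, "U": 15, "X": 15}


@dataclass
class OligoSet:
    """The five strands embodying one tag bit, all written 5'->3'."""

    bit_index: int
    tag_strand: str
    blocker_strand: str
    probe_strand: str
    anchor_strand: str
    fluorophore_strand: str

    def strands(self) -> dict[str, str]:
        return {
            "anchor": self.anchor_strand,
            "blocker": self.blocker_strand,
            "fluorophore": self.fluorophore_strand,
            "probe": self.probe_strand,
            "tag": self.tag_strand,
        }


@dataclass
class BarcodeLibrary:
    """Validated orthogonal Si domains plus the shared T/U/X/F domains."""

    barcodes: list[str]
    params: DesignParams
    shared_domains: dict[str, str]
    complete: bool = True  # False when the greedy build exhausted candidates early

    def __len__(self) -> int:
        return len(self.barcodes)

    def validate(self) -> None:
        """Re-assert every library invariant from scratch (post-hoc audit)."""
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        for s in self.barcodes:
            if not passes_composition(s, self.params):
                raise ValueError(f"barcode {s} fails composition filter")
            if not passes_structure(s, self.params):
                raise ValueError(f"barcode {s} fails structure filter")
        for i, a in enumerate(self.barcodes):
            for b in self.barcodes[i + 1 :]:
                if max_shared_substring(a, b, True) > self.params.max_shared_substring:
                    raise ValueError(f"{a} / {b} share too long a substring")

    def to_json(self, path=None) -> str:
        p = self.params
        payload = {
            "barcodes": self.barcodes,
            "shared_domains": self.shared_domains,
            "complete": self.complete,
            "params": {
                "length": p.length,
                "alphabet": list(p.alphabet),
                "c_content_range": list(p.c_content_range),
                "max_run_AT": p.max_run_AT,
                "max_run_C": p.max_run_C,
                "max_shared_substring": p.max_shared_substring,
                "hairpin_stem_max": p.hairpin_stem_max,
                "min_loop": p.min_loop,
                "local_align_score_max": p.local_align_score_max,
                "candidate_count": p.candidate_count,
                "rng_seed": p.rng_seed,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BarcodeLibrary":
        if isinstance(source, Path) or (
            isinstance(source, str) and "{" not in source
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        pp = payload["params"]
        pp["alphabet"] = tuple(pp["alphabet"])
        pp["c_content_range"] = tuple(pp["c_content_range"])
        return cls(
            barcodes=payload["barcodes"],
            params=DesignParams(**pp),
            shared_domains=payload["shared_domains"],
            complete=payload["complete"],
        )


# ---------------------------------------------------------------------------
# per-sequence filters

def generate_candidates(params: DesignParams, rng=None) -> list[str]:
    """Uniform random sequences over the design alphabet; no filters applied."""
    rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    letters = np.array(sorted(params.alphabet))
    draws = rng.integers(0, len(letters), size=(params.candidate_count, params.length))
    return ["".join(row) for row in letters[draws]]


def passes_composition(seq: str, params: DesignParams) -> bool:
    """C-content window plus homopolymer-run limits on A/T and C.

    The alphabet has no G, so the "GC content" window reduces to the C
    fraction alone.
    """
    lo, hi = params.c_content_range
    frac_c = seq.count("C") / len(seq)
    if not (lo <= frac_c <= hi):
        return False
    if re.search("A{%d,}|T{%d,}" % (params.max_run_AT + 1, params.max_run_AT + 1), seq):
        return False
    if re.search("C{%d,}" % (params.max_run_C + 1), seq):
        return False
    return True


def longest_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Length of the longest intramolecular stem.

    A stem of length L is a pair of disjoint substrings, one the reverse
    complement of the other, separated by at least ``min_loop`` unpaired
    bases.  Brute force over all (start, length) pairs; fine for 20-mers.
    """
    n = len(seq)
    best = 0
    for L in range(n // 2, 0, -1):
        for i in range(n - 2 * L - min_loop + 1):
            if revcomp(seq[i : i + L]) in seq[i + L + min_loop :]:
                return L
    return best


def passes_structure(seq: str, params: DesignParams) -> bool:
    """Reject sequences that can fold back on themselves.

    True iff the longest self-complementary stem (loop >= ``min_loop``) is
    shorter than ``hairpin_stem_max``.  A longer stem always contains a stem
    of exactly that length with the same loop, so a single length check
    suffices.  ``params.structure_hook``, when set, overrides the decision
    (e.g. to delegate to a thermodynamic structure predictor).
    """
    if not seq:
        raise ValueError("empty sequence")
    if params.structure_hook is not None:
        return bool(params.structure_hook(seq))
    L = params.hairpin_stem_max
    n = len(seq)
    for i in range(n - 2 * L - params.min_loop + 1):
        if revcomp(seq[i : i + L]) in seq[i + L + params.min_loop :]:
            return False
    return True


# ---------------------------------------------------------------------------
# pairwise screens

def max_shared_substring(a: str, b: str, check_revcomp: bool = True) -> int:
    """Longest common substring length between two sequences.

    With ``check_revcomp`` the reverse complement of ``b`` is also scanned,
    since cross-hybridization is possible in either orientation.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best = _lcs_len(a, b)
    if check_revcomp:
        best = max(best, _lcs_len(a, revcomp(b)))
    return best


def _lcs_len(a: str, b: str) -> int:
    # rolling-row dynamic program over substring end positions
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _aligner(params: DesignParams) -> "PairwiseAligner":
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def local_align_screen(a: str, b: str, params: DesignParams) -> int:
    """Best Smith-Waterman local alignment score (match +1/mismatch -1/gap -2).

    Used downstream to reject a candidate whose score against any accepted
    library member exceeds ``params.local_align_score_max``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return int(_aligner(params).score(a, b))


# ---------------------------------------------------------------------------
# library construction

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _sample_shared_domain(rng, length: int, alphabet: Sequence[str], params) -> str:
    letters = np.array(sorted(alphabet))
    while True:
        seq = "".join(letters[rng.integers(0, len(letters), size=length)])
        frac_c = seq.count("C") / length
        if "G" in alphabet:  # 4-letter domain: count C+G
            frac_c = (seq.count("C") + seq.count("G")) / length
        if not (params.c_content_range[0] <= frac_c <= params.c_content_range[1]):
            continue
        if re.search("A{5,}|T{5,}|C{4,}|G{4,}", seq):
            continue
        if longest_hairpin_stem(seq, params.min_loop) >= params.hairpin_stem_max:
            continue
        return seq


def default_shared_domains(params: DesignParams, rng=None) -> dict[str, str]:
    """Sample the shared T (toehold), U (stabilizer) and X (fluorophore arm)
    domains with the same run/composition discipline as the barcodes.

    X may use all four letters (it never contacts tag strands); F is the dye
    position and carries no nucleotides.
    """
    rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    domains = {
        "T": _sample_shared_domain(rng, _SHARED_LENGTHS["T"], "ACT", params),
        "U": _sample_shared_domain(rng, _SHARED_LENGTHS["U"], "ACT", params),
        "X": _sample_shared_domain(rng, _SHARED_LENGTHS["X"], "ACGT", params),
        "F": "",
    }
    return domains


def build_library(
    params: DesignParams,
    target_size: int | None = 25,
    shared_domains: dict[str, str] | None = None,
) -> BarcodeLibrary:
    """Greedy orthogonal-library construction.

    Candidates are screened in generation order: composition, hairpin stem,
    then pairwise orthogonality against every accepted member (shared
    substring <= ``max_shared_substring`` in both orientations, and local
    alignment score <= ``local_align_score_max``).  Stops at ``target_size``
    accepted barcodes, or at candidate exhaustion (``complete=False``).

    The shared-substring threshold test uses an (m+1)-mer index over the
    accepted set (sense and reverse complement), which is exactly equivalent
    to thresholding the longest-common-substring length.
    """
    if target_size is not None and target_size < 1:
        raise ValueError("target_size must be >= 1")
    rng = np.random.default_rng(params.rng_seed)
    if shared_domains is None:
        shared_domains = default_shared_domains(params, rng)
    candidates = generate_candidates(params, rng)

    k = params.max_shared_substring + 1
    accepted: list[str] = []
    index: set[str] = set()  # k-mers of accepted members, both orientations
    aligner = _aligner(params)
    for cand in candidates:
        if target_size is not None and len(accepted) >= target_size:
            break
        if not passes_composition(cand, params):
            continue
        if not passes_structure(cand, params):
            continue
        if any(kmer in index for kmer in _kmers(cand, k)):
            continue
        if any(
            aligner.score(cand, m) > params.local_align_score_max for m in accepted
        ):
            continue
        accepted.append(cand)
        index |= _kmers(cand, k) | _kmers(revcomp(cand), k)

    complete = target_size is None or len(accepted) >= target_size
    return BarcodeLibrary(accepted, params, shared_domains, complete=complete)


# ---------------------------------------------------------------------------
# oligo assembly

def build_oligos(
    library: BarcodeLibrary, i: int, anchor_polyt_at_3prime: bool = True
) -> OligoSet:
    """Assemble the five strands for bit ``i`` (1-based).

    ``anchor_polyt_at_3prime`` places the 30-nt poly-T nitrocellulose-binding
    tail on the anchor's 3' end (the documented orientation); set False to
    put it at the 5' end instead.
    """
    if not (1 <= i <= len(library)):
        raise IndexError(f"bit index {i} out of range 1..{len(library)}")
    si = library.barcodes[i - 1]
    T = library.shared_domains["T"]
    U = library.shared_domains["U"]
    X = library.shared_domains["X"]
    F = library.shared_domains.get("F", "")
    polyt = "T" * 30
    anchor_core = revcomp(U) + revcomp(si)  # <U* Si*>
    return OligoSet(
        bit_index=i,
        tag_strand=revcomp(T) + revcomp(U) + revcomp(si),  # <T* U* Si*>
        blocker_strand=U + T,  # <U T>, identical for every bit
        probe_strand=X + si + U + T,  # <X Si U T>
        anchor_strand=(anchor_core + polyt) if anchor_polyt_at_3prime else (polyt + anchor_core),
        fluorophore_strand=F + revcomp(X),  # <F X*>
    )


def generate_decoys(library: BarcodeLibrary, n: int, rng_seed: int = 0) -> list[str]:
    """Random tag-format decoy strands ``<T* U* N20>``.

    Decoys share the universal T*.U* prefix with real tag strands but carry a
    uniformly random four-letter Si* domain, so they sequence like tag
    strands yet trigger no reporter.  They need not pass any design filter;
    the point is to inflate the 4^20 space an adversary must search.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng_seed)
    prefix = revcomp(library.shared_domains["T"]) + revcomp(library.shared_domains["U"])
    letters = np.array(list("ACGT"))
    length = library.params.length
    draws = rng.integers(0, 4, size=(n, length))
    return [prefix + "".join(row) for row in letters[draws]]


# ---------------------------------------------------------------------------
# FASTA I/O

def write_fasta(oligosets: Sequence[OligoSet], path) -> None:
    """Multi-FASTA export, one record per strand, sorted by (bit, role)."""
    if not oligosets:
        raise ValueError("no oligo sets to write")
    records = []
    for oset in sorted(oligosets, key=lambda o: o.bit_index):
        for role, seq in sorted(oset.strands().items()):
            if not seq:  # fluorophore strand with empty F still has X*; skip only truly empty
                continue
            records.append(
                SeqRecord(Seq(seq), id=f"bit{oset.bit_index:03d}|{role}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[OligoSet]:
    """Inverse of :func:`write_fasta`."""
    strands: dict[int, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        bit_part, role = rec.id.split("|")
        idx = int(bit_part.removeprefix("bit"))
        strands.setdefault(idx, {})[role] = str(rec.seq)
    out = []
    for idx in sorted(strands):
        s = strands[idx]
        out.append(
            OligoSet(
                bit_index=idx,
                tag_strand=s["tag"],
                blocker_strand=s["blocker"],
                probe_strand=s["probe"],
                anchor_strand=s["anchor"],
                fluorophore_strand=s.get("fluorophore", ""),
            )
        )
    return out
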