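"""Species-level model of hybridization-encoded (HyEn) tags.

A codeword bit is embodied by the hybridization state of a shared tag strand
``<T* U* Si*>``: single-stranded means 1, blocked by the universal blocker
``<U T>`` into a partial duplex means 0.  Because every bit uses the same
blocker and the same T*.U* prefix, the strand *content* of a tag is nearly
independent of the message — only the duplex states carry it.  This module
simulates the displacement readout of such tags and the two forgery attacks
that the encoding is designed to defeat:

* thermal/amplification attack — melting dissociates all blockers, and on
  re-annealing they redistribute uniformly over the identical binding sites,
  erasing bit identity;
* read-and-rewrite attack — sequencing sees the same strand set for every
  codeword (with at least one zero), so the message cannot be read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .design import BarcodeLibrary, build_oligos

__all__ = [
    "TagMixSpec",
    "KineticsParams",
    "NoiseModel",
    "DNATag",
    "assemble_tag",
    "displacement_extent",
    "simulate_readout",
    "thermal_attack",
    "naive_tag_attack_contrast",
    "sequencing_view",
]


@dataclass(frozen=True)
class TagMixSpec:
    """Wet-mix composition of one tag.

    Concentrations in µM, volume in µL.  ``trehalose_M`` is metadata (the
    drying stabilizer); ``dried_without_trehalose`` selects the high-noise
    readout preset in :class:`NoiseModel`.
    """

    per_bit_concentration: float = 4.0  # µM per tag strand
    blocker_excess: float = 1.15  # blocker:tag ratio used when annealing bit 0s
    volume: float = 60.0  # µL
    trehalose_M: float = 0.7
    dried_without_trehalose: bool = False

    def __post_init__(self):
        if self.per_bit_concentration <= 0 or self.volume <= 0:
            raise ValueError("concentration and volume must be positive")
        if self.blocker_excess < 1:
            raise ValueError("blocker_excess must be >= 1")


@dataclass(frozen=True)
class KineticsParams:
    """Pseudo-first-order displacement kinetics.

    ``rate_constant`` (per µM per minute) is calibrated so that the reaction
    half-life at the default 4 µM tag-strand concentration is 2 minutes —
    comfortably within the observed <5 min half-life, with ~97% saturation by
    10 minutes.  ``incubation_time`` is the readout reaction time in minutes.
    """

    rate_constant: float = math.log(2) / 2.0 / 4.0  # per µM per min
    incubation_time: float = 20.0  # min
    saturation_decay: float = 1.0  # max achievable normalized decay

    def __post_init__(self):
        if min(self.rate_constant, self.incubation_time, self.saturation_decay) <= 0:
            raise ValueError("kinetics parameters must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Per-spot decay noise, matched to calibration-data distributions.

    A spot with ideal displacement extent ``e`` draws its observed
    normalized decay from TruncNormal(mu1*e, sigma0 + (sigma1-sigma0)*e)
    on [0, 1].  At e=0 this is exactly the half-normal bit-0 model
    (spurious decay of an unreacted spot); at e=1 it is the truncated
    Gaussian bit-1 model.
    """

    mu1: float = 0.70  # mean decay of a fully reacted spot
    sigma1: float = 0.15
    sigma0: float = 0.10

    @classmethod
    def dried_without_trehalose(cls) -> "NoiseModel":
        """Preset for tags dried without the trehalose stabilizer: bit-0
        duplexes partially denature, inflating spurious decay well past the
        3-bit correction radius on average."""
        return cls(sigma0=0.35)

    def sample(self, extents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        e = np.asarray(extents, dtype=float)
        loc = self.mu1 * e
        scale = self.sigma0 + (self.sigma1 - self.sigma0) * e
        a = (0.0 - loc) / scale
        b = (1.0 - loc) / scale
        return truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)


@dataclass
class DNATag:
    """Physical embodiment of a codeword.

    ``blocked_fraction[i]`` is the fraction of bit i's tag strands bound by a
    blocker: 1.0 for an intact 0 bit, 0.0 for an intact 1 bit, fractional
    after an attack.  ``total_blocker`` is the total blocker amount in units
    of one bit's tag-strand amount (bound + free), conserved by attacks.
    """

    codeword: np.ndarray
    bit_states: list[str]  # 'SS' (bit 1) or 'DS' (bit 0)
    blocked_fraction: np.ndarray
    mix: TagMixSpec
    library: BarcodeLibrary
    total_blocker: float = 0.0
    attacked: bool = False

    @property
    def n_bits(self) -> int:
        return len(self.codeword)

    @property
    def n_zero(self) -> int:
        return int((self.codeword == 0).sum())

    @property
    def free_blocker(self) -> float:
        return self.total_blocker - float(self.blocked_fraction.sum())


def assemble_tag(codeword, library: BarcodeLibrary, mix: TagMixSpec | None = None) -> DNATag:
    """Mix tag strands per the codeword: bit 1 -> single-stranded, bit 0 ->
    pre-annealed blocker duplex (with ``blocker_excess`` blocker per 0 bit)."""
    codeword = np.asarray(codeword, dtype=np.uint8)
    if mix is None:
        mix = TagMixSpec()
    if len(codeword) > len(library):
        raise ValueError(
            f"codeword has {len(codeword)} bits but library holds {len(library)} barcodes"
        )
    states = ["SS" if b else "DS" for b in codeword]
    blocked = np.where(codeword == 1, 0.0, 1.0).astype(float)
    n0 = int((codeword == 0).sum())
    return DNATag(
        codeword=codeword,
        bit_states=states,
        blocked_fraction=blocked,
        mix=mix,
        library=library,
        total_blocker=mix.blocker_excess * n0,
    )


def displacement_extent(
    blocked_fraction: float,
    matching: bool,
    kinetics: KineticsParams,
    t: float | None = None,
    concentration: float = 4.0,
) -> float:
    """Fraction of a reporter spot's fluorophore displaced after time t.

    Orthogonal (non-matching) strands are inert.  Otherwise the unblocked
    fraction of the bit's strands drives a pseudo-first-order approach to
    ``saturation_decay`` with rate proportional to the free-strand
    concentration ("reaction speed is semi-proportional to DNA
    concentration"); a fully blocked bit never reacts.
    """
    f = float(blocked_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError("blocked_fraction must be in [0, 1]")
    if t is None:
        t = kinetics.incubation_time
    if t < 0:
        raise ValueError("t must be >= 0")
    if not matching:
        return 0.0
    free_conc = (1.0 - f) * concentration
    k_eff = kinetics.rate_constant * free_conc
    return (1.0 - f) * kinetics.saturation_decay * (1.0 - math.exp(-k_eff * t))


def simulate_readout(
    tag: DNATag,
    n_spots: int = 25,
    spot_to_bit: list[int | None] | None = None,
    noise: NoiseModel | None = None,
    kinetics: KineticsParams | None = None,
    rng_seed: int | None = 0,
    t: float | None = None,
) -> np.ndarray:
    """Ground-truth normalized decay for each ticket spot (row-major order).

    ``spot_to_bit[s]`` maps spot s to a 0-based codeword bit, or None for an
    unassigned spot, which stays bright like an intact 0 bit.  Noiseless
    (``noise=None``) output is the pure displacement extent; with a noise
    model, per-spot decays are drawn from its extent-conditional
    distribution, deterministically for a given seed.
    """
    if kinetics is None:
        kinetics = KineticsParams()
    if spot_to_bit is None:
        spot_to_bit = [i if i < tag.n_bits else None for i in range(n_spots)]
    if len(spot_to_bit) != n_spots:
        raise ValueError("spot_to_bit length must equal n_spots")
    mapped = [b for b in spot_to_bit if b is not None]
    if mapped and max(mapped) >= tag.n_bits:
        raise ValueError("spot_to_bit references a bit beyond the codeword")
    extents = np.zeros(n_spots)
    for s, b in enumerate(spot_to_bit):
        if b is None:
            continue
        extents[s] = displacement_extent(
            tag.blocked_fraction[b],
            matching=True,
            kinetics=kinetics,
            t=t,
            concentration=tag.mix.per_bit_concentration,
        )
    if noise is None:
        return extents
    rng = np.random.default_rng(rng_seed)
    return noise.sample(extents, rng)


# ---------------------------------------------------------------------------
# forgery attacks

def thermal_attack(
    tag: DNATag, rng_seed: int | None = None, molecules_per_bit: int | None = None
) -> DNATag:
    """Melt-and-reanneal model of a PCR/amplification attack.

    At 95 C every blocker dissociates; on cooling, blockers rebind uniformly
    across all tag strands (their T*.U* binding sites are identical), so each
    bit ends up with blocked fraction ``min(1, total_blocker / n_bits)`` and
    bit identity is erased.  ``molecules_per_bit`` switches on multinomial
    partitioning noise at that molecule count per bit; blocker amount is
    conserved either way.
    """
    n = tag.n_bits
    if tag.total_blocker == 0:  # all-ones tag: nothing to melt
        return replace(
            tag, blocked_fraction=tag.blocked_fraction.copy(), attacked=True
        )
    uniform = tag.total_blocker / n
    if molecules_per_bit is None:
        blocked = np.full(n, min(1.0, uniform))
    else:
        rng = np.random.default_rng(rng_seed)
        total_molecules = int(round(tag.total_blocker * molecules_per_bit))
        counts = rng.multinomial(total_molecules, np.full(n, 1.0 / n))
        blocked = np.minimum(1.0, counts / molecules_per_bit)
    return replace(
        tag,
        blocked_fraction=blocked,
        bit_states=["DS" if f > 0.5 else "SS" for f in blocked],
        attacked=True,
    )


def naive_tag_attack_contrast(presence: np.ndarray, amplification: float = 1e6) -> dict:
    """Contrast case: a presence/absence tag (prior-art scheme) survives
    amplification.

    Bits are encoded purely as which strands are present, so multiplying all
    present species by any factor leaves the binarized readout unchanged —
    the amplification forgery succeeds.
    """
    presence = np.asarray(presence, dtype=float)
    if amplification <= 0:
        raise ValueError("amplification factor must be positive")
    amplified = presence * amplification
    return {
        "readout_before": (presence > 0).astype(np.uint8),
        "readout_after": (amplified > 0).astype(np.uint8),
        "forgery_succeeds": True,
    }


def sequencing_view(tag: DNATag, decoys: list[str] = ()) -> frozenset[str]:
    """The strand-sequence set an adversary obtains by sequencing the tag.

    Hybridization state is invisible to sequencing: the set contains every
    tag strand present plus the universal blocker iff any bit is 0.  All
    codewords with at least one zero over the same library therefore yield
    the identical set.
    """
    seqs = set()
    for i in range(tag.n_bits):
        seqs.add(build_oligos(tag.library, i + 1).tag_strand)
    if tag.n_zero >= 1:
        seqs.add(build_oligos(tag.library, 1).blocker_strand)
    seqs.update(decoys)
    return frozenset(seqs)
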