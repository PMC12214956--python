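"""End-to-end orchestration: ID -> ECC -> tag -> (attack) -> images -> bits -> ID.

:func:`run_end_to_end` executes the whole simulated round trip for one
configuration and returns (optionally writes) a JSON report with every
intermediate quantity and the seeds that produced it, so a run is fully
reproducible.  :func:`make_fixture` writes the small deterministic artifacts
the test-suite and examples use.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import calibration, imaging, tags
from .design import BarcodeLibrary, DesignParams, build_library, build_oligos, write_fasta
from .ecc import LinearCode, default_code, identity_code
from .imaging import PipelineConfig, RenderMeta, TicketLayout

__all__ = ["RunConfig", "run_end_to_end", "make_fixture", "default_library"]

_LIBRARY_CACHE: dict[tuple, BarcodeLibrary] = {}


def default_library(n_barcodes: int = 25, rng_seed: int = 0) -> BarcodeLibrary:
    """A validated orthogonal library big enough for a full 5x5 ticket.

    Cached per (size, seed): the greedy build is deterministic, so reuse is
    safe and keeps batch simulations fast.
    """
    key = (n_barcodes, rng_seed)
    if key not in _LIBRARY_CACHE:
        _LIBRARY_CACHE[key] = build_library(
            DesignParams(rng_seed=rng_seed), target_size=n_barcodes
        )
    return _LIBRARY_CACHE[key]


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end simulation run.

    ``dataword`` of None draws a random 12-bit ID from ``seed``.  ``attack``
    is 'none' or 'thermal'.  ``noise`` False gives the noiseless pipeline.
    """

    dataword: tuple[int, ...] | None = None
    attack: str = "none"
    noise: bool = True
    dried_without_trehalose: bool = False
    seed: int = 0
    library_seed: int = 0
    threshold: float = 0.38
    normalization: str = "relative"
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_end_to_end(
    config: RunConfig,
    library: BarcodeLibrary | None = None,
    code: LinearCode | None = None,
) -> dict:
    """Encode, embody, optionally attack, image, and decode one tag."""
    if config.attack not in ("none", "thermal"):
        raise ValueError(f"unknown attack {config.attack!r}")
    rng = np.random.default_rng(config.seed)
    code = code or default_code()
    library = library or default_library(rng_seed=config.library_seed)

    dataword = (
        np.asarray(config.dataword, dtype=np.uint8)
        if config.dataword is not None
        else rng.integers(0, 2, size=code.k).astype(np.uint8)
    )
    codeword = code.encode(dataword)

    mix = tags.TagMixSpec(dried_without_trehalose=config.dried_without_trehalose)
    tag = tags.assemble_tag(codeword, library, mix)
    if config.attack == "thermal":
        tag = tags.thermal_attack(tag)

    layout = TicketLayout.for_bits(code.n)
    noise = None
    if config.noise:
        noise = (
            tags.NoiseModel.dried_without_trehalose()
            if config.dried_without_trehalose
            else tags.NoiseModel()
        )
    readout_seed = int(rng.integers(0, 2**31 - 1))
    decays = tags.simulate_readout(
        tag,
        n_spots=layout.n_spots,
        spot_to_bit=list(layout.spot_to_bit),
        noise=noise,
        rng_seed=readout_seed,
    )
    meta = RenderMeta(noise_sigma=2.0 if config.noise else 0.0)
    render_seed = int(rng.integers(0, 2**31 - 1))
    pre, post = imaging.images_from_decays(layout, decays, meta, render_seed)
    pipe = PipelineConfig(threshold=config.threshold, normalization=config.normalization)
    result = imaging.read_ticket(pre, post, code, pipe)

    true_distance = int((result.codeword_bits ^ codeword).sum())
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "readout_seed": readout_seed,
        "render_seed": render_seed,
        "attack": config.attack,
        "dataword": dataword.tolist(),
        "codeword": codeword.tolist(),
        "codeword_bits_read": result.codeword_bits.tolist(),
        "raw_distance_to_truth": true_distance,
        "nearest_codeword_distance": result.decode.distance,
        "decoded_dataword": result.decode.dataword.tolist(),
        "decode_guaranteed": result.decode.guaranteed,
        "decode_ambiguous": result.decode.ambiguous,
        "decode_correct": bool(np.array_equal(result.decode.dataword, dataword)),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pre.save(out / "pre.png")
        post.save(out / "post.png")
        result.decays.to_csv(out / "decay_matrix.csv")
        result.to_json(out / "readout.json")
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def make_fixture(kind: str, seed: int, outdir) -> list[Path]:
    """Write deterministic fixture files: image pairs, calibration CSV or a
    small validated library + FASTA."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind in ("clean_ticket", "attacked_ticket"):
        run = RunConfig(
            attack="thermal" if kind == "attacked_ticket" else "none",
            seed=seed,
            outdir=str(out),
        )
        run_end_to_end(run)
        written = [out / f for f in ("pre.png", "post.png", "decay_matrix.csv",
                                     "readout.json", "report.json")]
    elif kind == "calibration_set":
        rng = np.random.default_rng(seed)
        noise = tags.NoiseModel()
        n = 500
        v1 = noise.sample(np.ones(n), rng)
        v0 = noise.sample(np.zeros(n), rng)
        import pandas as pd

        frame = pd.DataFrame(
            {
                "value": np.concatenate([v1, v0]),
                "label": ["bit1"] * n + ["bit0"] * n,
            }
        )
        path = out / "calibration.csv"
        frame.to_csv(path, index=False)
        written = [path]
    elif kind == "library_small":
        lib = build_library(DesignParams(rng_seed=seed), target_size=25)
        lib.validate()
        jpath = out / "library.json"
        lib.to_json(jpath)
        fpath = out / "oligos.fasta"
        write_fasta([build_oligos(lib, i + 1) for i in range(len(lib))], fpath)
        written = [jpath, fpath]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


def calibrate_from_csv(path, prior1: float = 0.5) -> dict:
    """Fit both decay distributions from a (value,label) CSV and return the
    Bayes-optimal threshold alongside the fitted parameters."""
    import pandas as pd

    frame = pd.read_csv(path)
    v1 = frame.loc[frame["label"] == "bit1", "value"].to_numpy()
    v0 = frame.loc[frame["label"] == "bit0", "value"].to_numpy()
    fit1 = calibration.fit_bit1(v1)
    fit0 = calibration.fit_bit0(v0)
    t = calibration.optimal_threshold(fit1, fit0, prior1)
    report = calibration.misclassification_report(v1, v0, t)
    return {
        "bit1": {"mu": fit1.mu, "sigma": fit1.sigma, "n": fit1.n},
        "bit0": {"sigma": fit0.sigma, "n": fit0.n},
        "optimal_threshold": t,
        **{f"at_threshold_{k}": v for k, v in report.items()},
    }
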