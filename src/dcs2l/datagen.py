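"""Training-corpus synthesis over the two-layer parameter grid.

Enumerates the simulation grid (brain optics × extracerebral thickness ×
brain Db × extracerebral-to-brain Db fraction), renders clean two-layer g2
curves on the 31-lag grid, corrupts them at three noise levels, and packages
(scaled noisy curve, CBFi×10⁶ label) pairs.  Also provides the scenario
waveforms (pulsatile brain flow over a ramping scalp flow) used for test
data synthesis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward_models import (
    DEFAULT_LAGS,
    InvalidParameterError,
    LayerOptics,
    TwoLayerMedium,
    g1_twolayer,
    g2_from_g1,
)
from .noise import SigmaProfile, draw_noise, scale_values


@dataclass(frozen=True)
class GridSpec:
    """Axes of the two-layer training grid.

    Defaults reproduce the full simulation grid: 5 brain μa × 5 brain μs' ×
    8 thicknesses × 100 brain Db × 20 Db fractions = 400,000 media, with the
    extracerebral optics, ρ and β held fixed.  ``Db_extra`` is always
    ``fraction × Db_brain``.
    """

    brain_mua: tuple = tuple(np.round(np.arange(0.005, 0.0251, 0.005), 4))
    brain_musp: tuple = tuple(np.round(np.arange(0.9, 1.31, 0.1), 2))
    thickness: tuple = tuple(float(t) for t in range(8, 16))
    Db_brain: tuple = tuple(5e-7 * np.arange(1, 101))
    extra_fraction: tuple = tuple(np.linspace(0.05, 0.3, 20))
    extra_mua: float = 0.019
    extra_musp: float = 0.86
    rho: float = 35.0
    beta: float = 0.5

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return (len(self.brain_mua), len(self.brain_musp), len(self.thickness),
                len(self.Db_brain), len(self.extra_fraction))

    def __len__(self) -> int:
        return math.prod(self.shape)

    @classmethod
    def ci_profile(cls) -> "GridSpec":
        """Reduced 2×2×2×10×4 grid (320 media) for minutes-scale pipelines."""
        return cls(
            brain_mua=(0.005, 0.025),
            brain_musp=(0.9, 1.3),
            thickness=(8.0, 15.0),
            Db_brain=tuple(np.linspace(5e-7, 5e-5, 10)),
            extra_fraction=tuple(np.linspace(0.05, 0.3, 4)),
        )


def medium_from_indices(spec: GridSpec, idx: tuple[int, int, int, int, int]) -> TwoLayerMedium:
    """The medium at one grid point (loop order: μa ▸ μs' ▸ thickness ▸ Db ▸ fraction)."""
    i, j, k, p, q = idx
    Db_brain = spec.Db_brain[p]
    return TwoLayerMedium(
        layer1=LayerOptics(spec.extra_mua, spec.extra_musp,
                           spec.extra_fraction[q] * Db_brain,
                           thickness=spec.thickness[k]),
        layer2=LayerOptics(spec.brain_mua[i], spec.brain_musp[j], Db_brain),
        rho=spec.rho,
        beta=spec.beta,
    )


def iter_grid_indices(spec: GridSpec):
    """Yield grid indices in the documented Cartesian loop order."""
    return np.ndindex(spec.shape)


def build_parameter_grid(spec: GridSpec) -> list[TwoLayerMedium]:
    """Materialize the full ordered list of media of the grid.

    For the full 400,000-point grid prefer :func:`iter_grid_indices` with
    :func:`medium_from_indices` to keep memory bounded.
    """
    return [medium_from_indices(spec, idx) for idx in iter_grid_indices(spec)]


# ---------------------------------------------------------------------------
# training set
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Paired (scaled noisy 31-lag curve, CBFi×10⁶ label) samples.

    ``provenance`` records per-sample grid index, noise level tag and seed so
    every label is re-derivable from its generating grid point.
    """

    inputs: np.ndarray
    labels: np.ndarray
    lags: np.ndarray = field(default_factory=lambda: DEFAULT_LAGS.copy())
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.float32)
        if self.inputs.shape[0] != self.labels.shape[0]:
            raise InvalidParameterError("inputs and labels must align")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def save(self, out_dir: str | Path, shard_size: int = 100_000) -> None:
        """Write float32 shards plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n = len(self)
        shards = []
        for s, start in enumerate(range(0, n, shard_size)):
            sl = slice(start, min(start + shard_size, n))
            fname = f"shard_{s:04d}.npz"
            np.savez(out / fname, inputs=self.inputs[sl], labels=self.labels[sl])
            shards.append(fname)
        manifest = {
            "n_samples": n,
            "n_lags": int(self.inputs.shape[1]),
            "lags_s": self.lags.tolist(),
            "shards": shards,
            "provenance": self.provenance,
        }
        (out / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainingSet":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        parts = [np.load(out / s) for s in manifest["shards"]]
        return cls(
            inputs=np.concatenate([p["inputs"] for p in parts]),
            labels=np.concatenate([p["labels"] for p in parts]),
            lags=np.asarray(manifest["lags_s"]),
            provenance=manifest.get("provenance", []),
        )


def clean_grid_curves(spec: GridSpec, lags: np.ndarray = DEFAULT_LAGS,
                      **quad_kw) -> np.ndarray:
    """Clean (unscaled) g2 curves for every grid point, in loop order."""
    qkw = dict(check=False)
    qkw.update(quad_kw)
    out = np.empty((len(spec), lags.size))
    for row, idx in enumerate(iter_grid_indices(spec)):
        m = medium_from_indices(spec, idx)
        out[row] = g2_from_g1(g1_twolayer(m, lags, **qkw), m.beta)
    return out


def generate_training_set(spec: GridSpec, levels: dict[str, SigmaProfile] | list[SigmaProfile],
                          seed: int, lags: np.ndarray = DEFAULT_LAGS,
                          **quad_kw) -> TrainingSet:
    """Render the full corpus: every grid medium × every noise level.

    For each medium the clean two-layer g2 curve is scaled, noise of each
    level is added, and the noisy curve rescaled to [1, 1.5]; the label is
    the generating Db_brain × 10⁶.  Total sample count is |grid| × n_levels.
    Regeneration with the same seed is bit-identical.
    """
    if isinstance(levels, dict):
        levels = list(levels.values())
    rng = np.random.default_rng(seed)
    clean = clean_grid_curves(spec, lags, **quad_kw)
    n_clean = clean.shape[0]
    scaled = scale_values(clean)
    inputs = np.empty((n_clean * len(levels), lags.size), dtype=np.float32)
    labels = np.empty(n_clean * len(levels), dtype=np.float32)
    prov = []
    db_index = [idx[3] for idx in iter_grid_indices(spec)]
    for li, level in enumerate(levels):
        noisy = scaled + draw_noise(level, n_clean, rng)
        sl = slice(li * n_clean, (li + 1) * n_clean)
        inputs[sl] = scale_values(noisy)
        labels[sl] = np.asarray([spec.Db_brain[p] for p in db_index]) * 1e6
        prov.extend({"grid_row": r, "level": level.level_tag, "seed": seed}
                    for r in range(n_clean))
    return TrainingSet(inputs=inputs, labels=labels, lags=lags, provenance=prov)


# ---------------------------------------------------------------------------
# scenario waveforms
# ---------------------------------------------------------------------------

def pulsatile_scenario(n_samples: int = 500,
                       brain_range: tuple[float, float] = (3e-6, 9e-6),
                       scalp_ramp: tuple[float, float] = (5e-7, 1.5e-6),
                       seed: int | None = None,
                       beats: float | None = None,
                       systole_fraction: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac-like brain-flow waveform over a linearly ramping scalp flow.

    The brain series is an asymmetric raised-cosine pulse train — a fast
    systolic upstroke occupying ``systole_fraction`` of each beat and a
    slower diastolic decay — rescaled to span ``brain_range`` exactly.  The
    scalp series ramps linearly between the endpoints of ``scalp_ramp``.
    ``seed`` is accepted for interface symmetry; the default waveform is
    deterministic.
    """
    if n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    if beats is None:
        beats = max(1.0, n_samples / 50.0)  # ~50 samples per beat
    phase = (np.linspace(0.0, beats, n_samples, endpoint=False) % 1.0)
    up = phase < systole_fraction
    wave = np.empty(n_samples)
    wave[up] = 0.5 - 0.5 * np.cos(np.pi * phase[up] / systole_fraction)
    wave[~up] = 0.5 + 0.5 * np.cos(np.pi * (phase[~up] - systole_fraction)
                                   / (1.0 - systole_fraction))
    lo, hi = brain_range
    wave = (wave - wave.min()) / (wave.max() - wave.min())
    brain = lo + (hi - lo) * wave
    scalp = np.linspace(scalp_ramp[0], scalp_ramp[1], n_samples)
    return brain, scalp
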