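"""Synthetic reference datasets with the statistical structure of in vivo
leukocyte track data.

No public track deposits exist for the imaging datasets this package's
methods were designed around, so these generators double as demo data and
test substrate: heterogeneous inverse-coupled CRW cells walked through the
finite imaging volume produce hundreds of tracks with ~24–27 observations
each, a wide spread of track lengths, a negative correlation between
observation count and median speed, and a negative step-level correlation
between translational and turn speed — the qualitative signatures of the
real data.

Default generator parameters are hand-tuned demo values chosen so pooled
speed medians land in the leukocyte-plausible 5–15 µm/min range; they are
not estimates of any real cell population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaConfig, run_replicate
from .tracks import Track, TrackDataset
from .walkers import WalkerParams

__all__ = ["FixturePreset", "generate_reference_dataset", "PRESETS"]

#: Demo IHeteroCRW generator: heterogeneous speeds/turns with inverse coupling.
_DEFAULT_GENERATOR = WalkerParams(
    "iheteroCRW",
    (
        150.0, 90.0, 60.0, 20.0,  # turn hyper-params (°/min)
        10.0, 5.0, 3.0, 1.0,      # translational hyper-params (µm/min)
        2.0,                      # inverse-coupling exponent β
    ),
)


@dataclass(frozen=True)
class FixturePreset:
    """Recipe for one reference dataset."""

    name: str
    n_tracks: int
    dt: float  # sampling interval, s
    duration: float  # imaging session length, s
    generator: WalkerParams = _DEFAULT_GENERATOR
    n_cells: int = 200

    def __post_init__(self):
        if self.n_tracks < 1 or self.dt <= 0 or self.duration < self.dt:
            raise ValueError("invalid fixture preset")

    def arena(self, **overrides) -> ArenaConfig:
        return ArenaConfig(
            record_interval=self.dt,
            duration=self.duration,
            n_cells=self.n_cells,
            **overrides,
        )


PRESETS = {
    # in-vivo-like presets: T cells sampled every 35 s for ~30 min,
    # neutrophils every 45 s for ~45 min
    "tcell-like": FixturePreset("tcell-like", n_tracks=751, dt=35.0, duration=1890.0),
    "neutrophil-like": FixturePreset("neutrophil-like", n_tracks=1017, dt=45.0, duration=2700.0),
    "smoke": FixturePreset("smoke", n_tracks=5, dt=30.0, duration=900.0, n_cells=30),
}


def generate_reference_dataset(
    preset: FixturePreset, seed: int = 0, max_replicates: int = 200
) -> TrackDataset:
    """Run arena replicates with the preset generator until the requested
    number of tracks is banked; truncates to exactly ``n_tracks``."""
    ss = np.random.SeedSequence(seed)
    banked: list[Track] = []
    cfg = preset.arena()
    for r in range(max_replicates):
        rng = np.random.default_rng(ss.spawn(1)[0])
        res = run_replicate(preset.generator, cfg, rng)
        for t in res.tracks:
            banked.append(Track(f"r{r}_{t.track_id}", t.positions, t.dt))
        if len(banked) >= preset.n_tracks:
            return TrackDataset(banked[: preset.n_tracks], label=preset.name)
    raise RuntimeError(
        f"banked only {len(banked)}/{preset.n_tracks} tracks in "
        f"{max_replicates} replicates; increase duration or cell count"
    )
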