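"""3D continuous-space, discrete-time agent-based arena.

Cells are non-overlapping spheres walking through a padded simulation
domain; only positions inside the central 412×412×100 µm tracked volume are
recorded, reproducing the finite-imaging-volume observation process that
biases in vivo track data (fast, persistent cells exit quickly and are
observed fewer times).  A cell leaving the tracked volume closes its track;
re-entry opens a new track id, as an imaging pipeline would see it.

Presets mirror the two imaging settings: T cells recorded every 30 s for
30 min, neutrophils every 45 s for 50 min.  The Lévy walk advances its
internal run clock every 3 s regardless, while recording stays at the
preset interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .tracks import Track, TrackDataset
from .walkers import LEVY_UPDATE_S, WalkerCohort, WalkerParams

__all__ = ["ArenaConfig", "SimulationResult", "run_replicate", "run_ensemble", "NoTracksError"]

TRACKED_VOLUME_UM = (412.0, 412.0, 100.0)


class NoTracksError(RuntimeError):
    """The observation process yielded no usable (>= 2 point) tracks."""


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and schedule.

    The simulation domain is the tracked volume padded by ``domain_margin``
    on every face (off-camera space, reflecting boundaries); cell count,
    radius and margin are not biologically pinned and are configurable.
    """

    record_interval: float = 30.0
    duration: float = 1800.0
    update_interval: float | None = None  # defaults to record_interval (Lévy: 3 s)
    tracked_volume: tuple = TRACKED_VOLUME_UM
    domain_margin: float = 50.0
    n_cells: int = 200
    cell_radius: float = 5.0

    def __post_init__(self):
        if self.duration < self.record_interval:
            raise ValueError("duration must cover at least one record interval")
        if self.n_cells < 1 or self.cell_radius <= 0 or self.domain_margin < 0:
            raise ValueError("invalid arena configuration")

    def updates_for(self, model: str) -> float:
        if self.update_interval is not None:
            upd = self.update_interval
        else:
            upd = LEVY_UPDATE_S if model == "levy" else self.record_interval
        ratio = self.record_interval / upd
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_interval must be an integer multiple of update_interval")
        return upd

    @classmethod
    def preset(cls, name: str, **overrides) -> "ArenaConfig":
        if name == "tcell":
            base = cls(record_interval=30.0, duration=1800.0)
        elif name == "neutrophil":
            base = cls(record_interval=45.0, duration=3000.0)
        else:
            raise ValueError(f"unknown preset {name!r} (tcell|neutrophil)")
        return replace(base, **overrides) if overrides else base


@dataclass
class SimulationResult:
    tracks: list[Track]
    config: ArenaConfig
    params: WalkerParams


def _initial_positions(cfg: ArenaConfig, rng: np.random.Generator) -> np.ndarray:
    lo = -cfg.domain_margin
    hi = np.array(cfg.tracked_volume) + cfg.domain_margin
    pos = rng.uniform(lo, hi, size=(cfg.n_cells, 3))
    min_sep = 2 * cfg.cell_radius
    for _ in range(200):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(min_sep, output_type="ndarray")
        if pairs.size == 0:
            return pos
        bad = np.unique(pairs[:, 1])  # resample the later cell of each pair
        pos[bad] = rng.uniform(lo, hi, size=(len(bad), 3))
    raise RuntimeError("could not place non-overlapping cells; arena too dense")


def _reflect(pos: np.ndarray, headings: np.ndarray, lo, hi) -> None:
    """Reflect positions exceeding the padded-domain walls, negating the
    normal heading component (in place)."""
    for ax in range(3):
        over = pos[:, ax] > hi[ax]
        under = pos[:, ax] < lo
        if over.any():
            pos[over, ax] = 2 * hi[ax] - pos[over, ax]
            headings[over, ax] *= -1
        if under.any():
            pos[under, ax] = 2 * lo - pos[under, ax]
            headings[under, ax] *= -1
        np.clip(pos[:, ax], lo, hi[ax], out=pos[:, ax])


def _resolve_collisions(
    pos: np.ndarray,
    prop: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequentially truncate proposed moves at first sphere contact.

    Broad phase via KD-tree on proposals; only cells with a potential
    contact are resolved one by one in a shuffled order (all others take
    their proposals directly, which the broad phase guarantees safe).
    """
    disp = prop - pos
    max_disp = float(np.max(np.linalg.norm(disp, axis=1))) if len(pos) else 0.0
    tree = cKDTree(prop)
    pairs = tree.query_pairs(min_sep + 2 * max_disp, output_type="ndarray")
    if pairs.size == 0:
        return prop
    suspects = np.unique(pairs)
    resolved = prop.copy()
    resolved[suspects] = pos[suspects]  # suspects start unmoved
    order = rng.permutation(suspects)
    sep2 = min_sep**2
    for i in order:
        others = np.delete(np.arange(len(pos)), i)
        a = pos[i] - resolved[others]
        b = disp[i]
        # |a + t b|^2 = sep^2 -> smallest root t in (0, 1]
        bb = b @ b
        t_hit = 1.0
        if bb > 0:
            ab = a @ b
            aa = np.einsum("ij,ij->i", a, a)
            disc = ab**2 - bb * (aa - sep2)
            cand = disc >= 0
            if cand.any():
                sqrt_d = np.sqrt(disc[cand])
                t1 = (-ab[cand] - sqrt_d) / bb
                t1 = t1[(t1 > 0) & (t1 <= 1.0)]
                if t1.size:
                    t_hit = float(min(t_hit, t1.min()))
        resolved[i] = pos[i] + max(t_hit - 1e-9, 0.0) * b
    return resolved


def run_replicate(
    model_params: WalkerParams, cfg: ArenaConfig, rng: np.random.Generator
) -> SimulationResult:
    """One arena replicate: initialise, walk, observe.

    Returns all recorded tracks of >= 2 points (a cell observed once
    cannot contribute a displacement and is discarded).
    """
    upd = cfg.updates_for(model_params.model)
    n_updates = int(round(cfg.duration / upd))
    rec_every = int(round(cfg.record_interval / upd))
    lo, hi = -cfg.domain_margin, np.array(cfg.tracked_volume) + cfg.domain_margin
    vol = np.array(cfg.tracked_volume)
    min_sep = 2 * cfg.cell_radius

    pos = _initial_positions(cfg, rng)
    cohort = WalkerCohort(model_params, cfg.n_cells, rng)

    tracks: list[Track] = []
    open_points: list[list | None] = [None] * cfg.n_cells
    track_counter = 0

    def record():
        nonlocal track_counter
        inside = np.all((pos >= 0) & (pos <= vol), axis=1)
        for c in range(cfg.n_cells):
            if inside[c]:
                if open_points[c] is None:
                    open_points[c] = []
                open_points[c].append(pos[c].copy())
            elif open_points[c] is not None:
                pts = open_points[c]
                open_points[c] = None
                if len(pts) >= 2:
                    tracks.append(
                        Track(f"c{c}_t{track_counter}", np.array(pts), cfg.record_interval)
                    )
                    track_counter += 1

    record()  # t = 0
    for u in range(1, n_updates + 1):
        headings, zeta, _phi = cohort.step(upd)
        prop = pos + headings * (zeta * upd / 60.0)[:, None]
        _reflect(prop, cohort.headings, lo, hi)
        pos = _resolve_collisions(pos, prop, min_sep, rng)
        if u % rec_every == 0:
            record()
    # close remaining residencies
    for c in range(cfg.n_cells):
        pts = open_points[c]
        if pts is not None and len(pts) >= 2:
            tracks.append(Track(f"c{c}_t{track_counter}", np.array(pts), cfg.record_interval))
            track_counter += 1
    return SimulationResult(tracks=tracks, config=cfg, params=model_params)


def run_ensemble(
    model_params: WalkerParams,
    cfg: ArenaConfig,
    n_replicates: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> TrackDataset:
    """Pool the tracks of independent replicates (distinct derived seeds,
    track ids made unique per replicate)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pooled: list[Track] = []
    for r, child in enumerate(ss.spawn(n_replicates)):
        res = run_replicate(model_params, cfg, np.random.default_rng(child))
        for t in res.tracks:
            pooled.append(Track(f"r{r}_{t.track_id}", t.positions, t.dt))
    if not pooled:
        raise NoTracksError(
            f"{model_params.model} ensemble produced no tracks of >= 2 points"
        )
    return TrackDataset(pooled, label=f"{model_params.model}-ensemble")
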