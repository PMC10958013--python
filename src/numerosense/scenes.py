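"""Synthetic bowl-play scene simulator.

A "scene" is a set of non-overlapping, axis-aligned bright squares on a dark
background — the contents of a bowl that an agent manipulates with three
actions: PUT (drop one object in), TAKE (remove one), SHAKE (re-randomize
positions without changing the count).  Sequences of such manipulations,
rendered to grayscale images, are the only training data the perception
network ever sees; balanced image sets with prescribed object counts are
used for the downstream numerosity analyses.

Two appearance regimes are supported:

* Regime A — identical squares (fixed size, full contrast), so total image
  intensity is a perfect linear covariate of the count.
* Regime B — size and contrast drawn uniformly from wide ranges, making
  mean intensity an ambiguous cue for the count.

All randomness flows through an explicit :class:`numpy.random.Generator`,
so identical seeds reproduce identical episodes bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np


class ActionKind(str, Enum):
    """The three bowl manipulations, serialized as single letters."""

    PUT = "P"
    TAKE = "T"
    SHAKE = "S"


class PlacementError(RuntimeError):
    """Rejection sampling could not place an object (scene too dense)."""


class InvalidActionError(ValueError):
    """An action was requested on a state where it is undefined."""


@dataclass(frozen=True)
class SceneObject:
    """One axis-aligned square: continuous center, side length, contrast."""

    center_x: float
    center_y: float
    size: float
    contrast: float

    def gap_to(self, other: "SceneObject") -> float:
        """Axis-aligned extent gap (Chebyshev-style) between two squares.

        Positive values are clear separation; the squares overlap iff the
        gap is negative on both axes, i.e. iff this value is negative.
        """
        reach = (self.size + other.size) / 2.0
        gx = abs(self.center_x - other.center_x) - reach
        gy = abs(self.center_y - other.center_y) - reach
        return max(gx, gy)


@dataclass(frozen=True)
class SceneState:
    """The set of objects currently in the bowl."""

    objects: tuple[SceneObject, ...] = ()

    @property
    def count(self) -> int:
        return len(self.objects)

    def min_gap(self) -> float:
        """Smallest pairwise extent gap; +inf for fewer than two objects."""
        objs = self.objects
        best = np.inf
        for i in range(len(objs)):
            for j in range(i + 1, len(objs)):
                best = min(best, objs[i].gap_to(objs[j]))
        return best


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and appearance statistics of one simulation regime.

    ``size_range`` and ``contrast_range`` are closed intervals sampled
    uniformly.  ``multiplicity_choices`` is the support of the per-action
    object multiplicity m (uniform over the tuple); the default degenerate
    (1,) gives precise single-object puts and takes.  ``max_objects`` caps
    episode counts during action sequences only — balanced test sets may
    request any count that physically fits.
    """

    image_size: int = 244
    margin: float = 3.0
    regime: str = "A"
    size_range: tuple[float, float] = (15.0, 15.0)
    contrast_range: tuple[float, float] = (1.0, 1.0)
    max_objects: int = 3
    multiplicity_choices: tuple[int, ...] = (1,)
    reshuffle_on_put_take: bool = True
    shake_resamples_appearance: bool = False
    retry_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.size_range[1] < self.size_range[0] or self.contrast_range[1] < self.contrast_range[0]:
            raise ValueError("size/contrast ranges must be non-empty")
        if not (0.0 < self.contrast_range[0] <= self.contrast_range[1] <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if self.max_objects < 1:
            raise ValueError("max_objects must be >= 1")
        if min(self.multiplicity_choices) < 1:
            raise ValueError("action multiplicity must be >= 1")
        if self.image_size < self.size_range[1]:
            raise ValueError("image too small for the largest object")
        if self.regime not in ("A", "B"):
            raise ValueError("regime must be 'A' or 'B'")


def regime_a(image_size: int = 244, max_objects: int = 3, **kw) -> SceneConfig:
    """Identical 15 px full-contrast squares (at 244 px; scaled otherwise)."""
    s = 15.0 * image_size / 244.0
    m = max(1.0, round(3.0 * image_size / 244.0))
    return SceneConfig(image_size=image_size, margin=m, regime="A",
                       size_range=(round(s), round(s)), contrast_range=(1.0, 1.0),
                       max_objects=max_objects, **kw)


def regime_b(image_size: int = 244, max_objects: int = 3, **kw) -> SceneConfig:
    """Variable size (10-30 px) and contrast (9.8-100%) squares."""
    lo, hi = 10.0 * image_size / 244.0, 30.0 * image_size / 244.0
    m = max(1.0, round(3.0 * image_size / 244.0))
    return SceneConfig(image_size=image_size, margin=m, regime="B",
                       size_range=(round(lo), round(hi)), contrast_range=(0.098, 1.0),
                       max_objects=max_objects, **kw)


def desk_config(regime: str = "A", max_objects: int = 3, **kw) -> SceneConfig:
    """Small 64 px preset for CPU-only studies.

    Object sizes are scaled with the image but kept at >= several pixels
    (regime A uses 6 px squares rather than the strictly proportional 4 px)
    so that rasterization and conv-stride phase noise do not dominate the
    count signal at this resolution.
    """
    if regime == "A":
        return SceneConfig(image_size=64, margin=1.0, regime="A",
                           size_range=(6.0, 6.0), contrast_range=(1.0, 1.0),
                           max_objects=max_objects, **kw)
    return SceneConfig(image_size=64, margin=1.0, regime="B",
                       size_range=(3.0, 8.0), contrast_range=(0.098, 1.0),
                       max_objects=max_objects, **kw)


# ---------------------------------------------------------------------------
# placement and actions

def _sample_position(existing: Sequence[SceneObject], size: float, contrast: float,
                     config: SceneConfig, rng: np.random.Generator) -> SceneObject:
    half = size / 2.0
    w = config.image_size
    for _ in range(config.retry_cap):
        cand = SceneObject(rng.uniform(half, w - half), rng.uniform(half, w - half),
                           size, contrast)
        if all(cand.gap_to(o) >= config.margin for o in existing):
            return cand
    raise PlacementError(
        f"could not place a {size:.1f}px object among {len(existing)} others "
        f"in a {w}px image after {config.retry_cap} attempts")


def place_object(state: SceneState, config: SceneConfig,
                 rng: np.random.Generator) -> SceneObject:
    """Draw one object uniformly: position anywhere in-bounds, appearance
    uniform over the regime ranges, subject to the pairwise clearance margin.
    """
    size = rng.uniform(*config.size_range)
    contrast = rng.uniform(*config.contrast_range)
    return _sample_position(state.objects, size, contrast, config, rng)


def _replace_all(objects: Sequence[SceneObject], config: SceneConfig,
                 rng: np.random.Generator, resample_appearance: bool) -> list[SceneObject]:
    """Re-draw positions for every object, keeping (or resampling) appearance."""
    placed: list[SceneObject] = []
    for o in objects:
        if resample_appearance:
            size = rng.uniform(*config.size_range)
            contrast = rng.uniform(*config.contrast_range)
        else:
            size, contrast = o.size, o.contrast
        placed.append(_sample_position(placed, size, contrast, config, rng))
    return placed


def _draw_multiplicity(config: SceneConfig, rng: np.random.Generator) -> int:
    choices = config.multiplicity_choices
    return int(choices[0]) if len(choices) == 1 else int(rng.choice(choices))


def apply_action(state: SceneState, action: ActionKind, config: SceneConfig,
                 rng: np.random.Generator) -> SceneState:
    """Apply one manipulation and return the new state.

    PUT adds m objects, TAKE removes m (error if none to take), SHAKE keeps
    the count and re-randomizes positions.  Retained objects are re-placed
    on PUT/TAKE as well when ``reshuffle_on_put_take`` is set, which is the
    default policy (it prevents trivial frame-differencing solutions).
    SHAKE preserves each object's size and contrast.
    """
    action = ActionKind(action)
    if action is ActionKind.SHAKE:
        new = _replace_all(state.objects, config, rng,
                           resample_appearance=config.shake_resamples_appearance)
        return SceneState(tuple(new))

    m = _draw_multiplicity(config, rng)
    if action is ActionKind.TAKE:
        if state.count < 1:
            raise InvalidActionError("TAKE is undefined on an empty scene")
        m = min(m, state.count)
        drop = set(rng.choice(state.count, size=m, replace=False).tolist())
        kept = [o for i, o in enumerate(state.objects) if i not in drop]
        if config.reshuffle_on_put_take:
            kept = _replace_all(kept, config, rng, resample_appearance=False)
        return SceneState(tuple(kept))

    # PUT; clip m so the episode cap is respected
    m = max(1, min(m, config.max_objects - state.count))
    kept = list(state.objects)
    if config.reshuffle_on_put_take:
        kept = _replace_all(kept, config, rng, resample_appearance=False)
    for _ in range(m):
        kept.append(_sample_position(kept, rng.uniform(*config.size_range),
                                     rng.uniform(*config.contrast_range), config, rng))
    return SceneState(tuple(kept))


def sample_valid_action(state: SceneState, config: SceneConfig,
                        rng: np.random.Generator) -> ActionKind:
    """Uniform draw over the actions valid at the current count.

    TAKE is excluded on an empty scene and PUT once the episode cap
    ``max_objects`` is reached; SHAKE is always valid.
    """
    valid = [ActionKind.PUT, ActionKind.TAKE, ActionKind.SHAKE]
    if state.count == 0:
        valid.remove(ActionKind.TAKE)
    if state.count >= config.max_objects:
        valid.remove(ActionKind.PUT)
    return valid[int(rng.integers(len(valid)))]


# ---------------------------------------------------------------------------
# rendering

def render(state: SceneState, config: SceneConfig) -> np.ndarray:
    """Rasterize a state to a float32 grayscale image, background 0.

    A pixel (row r, column c) has its center at (c + 0.5, r + 0.5); a pixel
    belongs to a square iff its center falls in the half-open extent
    [center - size/2, center + size/2) on both axes, so an integer-sized
    square always covers exactly size**2 pixels regardless of sub-pixel
    position.  Squares never overlap, so paint order is irrelevant.
    """
    w = config.image_size
    img = np.zeros((w, w), dtype=np.float32)
    for o in state.objects:
        x0 = max(0, int(np.ceil(o.center_x - o.size / 2 - 0.5)))
        x1 = min(w, int(np.ceil(o.center_x + o.size / 2 - 0.5)))
        y0 = max(0, int(np.ceil(o.center_y - o.size / 2 - 0.5)))
        y1 = min(w, int(np.ceil(o.center_y + o.size / 2 - 0.5)))
        img[y0:y1, x0:x1] = o.contrast
    return img


# ---------------------------------------------------------------------------
# episodes and test sets

@dataclass(frozen=True)
class ActionRecord:
    """One manipulation linking a before/after image pair."""

    action: ActionKind
    state_before: SceneState
    state_after: SceneState
    image_before: np.ndarray
    image_after: np.ndarray


def generate_training_sequence(config: SceneConfig, n_actions: int,
                               rng: np.random.Generator) -> list[ActionRecord]:
    """One play episode: start from an empty bowl, chain random valid actions.

    Consecutive records share frames (record i's after-image is record
    i+1's before-image, the same array object), so a length-n sequence
    holds n+1 distinct rendered frames and n labeled pairs.
    """
    if n_actions < 1:
        raise ValueError("n_actions must be >= 1")
    state = SceneState()
    img = render(state, config)
    records: list[ActionRecord] = []
    for _ in range(n_actions):
        action = sample_valid_action(state, config, rng)
        new_state = apply_action(state, action, config, rng)
        new_img = render(new_state, config)
        records.append(ActionRecord(action, state, new_state, img, new_img))
        state, img = new_state, new_img
    return records


def sequence_stream(config: SceneConfig, n_actions: int,
                    rng: np.random.Generator) -> Iterator[list[ActionRecord]]:
    """Endless stream of fresh play episodes (one per training mini-batch)."""
    while True:
        yield generate_training_sequence(config, n_actions, rng)


@dataclass
class LabeledImageSet:
    """Rendered images with ground-truth object counts (and full states)."""

    images: np.ndarray          # (N, H, W) float32
    counts: np.ndarray          # (N,) int
    states: list[SceneState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.counts)


def generate_balanced_test_set(config: SceneConfig, counts: Sequence[int],
                               n_per_count: int, rng: np.random.Generator,
                               scene_retries: int = 50) -> LabeledImageSet:
    """Directly place the requested number of objects — no action chains —
    yielding exactly ``n_per_count`` images per count (guaranteed balance).
    """
    images, labels, states = [], [], []
    for c in counts:
        for _ in range(n_per_count):
            for attempt in range(scene_retries):
                try:
                    objs: list[SceneObject] = []
                    for _ in range(c):
                        objs.append(_sample_position(
                            objs, rng.uniform(*config.size_range),
                            rng.uniform(*config.contrast_range), config, rng))
                    break
                except PlacementError:
                    if attempt == scene_retries - 1:
                        raise
            state = SceneState(tuple(objs))
            states.append(state)
            images.append(render(state, config))
            labels.append(c)
    return LabeledImageSet(np.stack(images), np.asarray(labels, dtype=int), states)


def records_image_set(records: Sequence[ActionRecord]) -> LabeledImageSet:
    """Collapse a sequence's distinct frames into a labeled image set."""
    images = [records[0].image_before] + [r.image_after for r in records]
    counts = [records[0].state_before.count] + [r.state_after.count for r in records]
    states = [records[0].state_before] + [r.state_after for r in records]
    return LabeledImageSet(np.stack(images), np.asarray(counts, dtype=int), states)


# ---------------------------------------------------------------------------
# covariate diagnostics

@dataclass
class IntensityReport:
    table: "object"             # pandas DataFrame: per-count intensity stats
    spearman_rho: float


def intensity_covariate_report(image_set: LabeledImageSet) -> IntensityReport:
    """Per-count mean-intensity distributions and the count-intensity rank
    correlation — quantifies how informative raw brightness is about number.
    """
    import pandas as pd
    from scipy.stats import spearmanr

    if len(image_set) == 0:
        raise ValueError("empty image set")
    mean_int = image_set.images.reshape(len(image_set), -1).mean(axis=1)
    df = pd.DataFrame({"count": image_set.counts, "mean_intensity": mean_int})
    table = df.groupby("count")["mean_intensity"].agg(["mean", "std", "min", "max"])
    if len(np.unique(image_set.counts)) > 1:
        rho = float(spearmanr(image_set.counts, mean_int).statistic)
    else:
        rho = float("nan")
    return IntensityReport(table=table, spearman_rho=rho)


# ---------------------------------------------------------------------------
# disk format: PNG frames + JSON-lines metadata

def _state_meta(state: SceneState) -> list[dict]:
    return [{"x": o.center_x, "y": o.center_y, "size": o.size, "contrast": o.contrast}
            for o in state.objects]


def save_sequence(records: Sequence[ActionRecord], out_dir: str | Path) -> None:
    """Write one episode: frame_%04d.png (8-bit grayscale) + metadata.jsonl."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iset = records_image_set(records)
    actions = [None] + [r.action.value for r in records]
    with open(out / "metadata.jsonl", "w") as fh:
        for i in range(len(iset)):
            frame = f"frame_{i:04d}.png"
            arr = np.clip(iset.images[i] * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / frame)
            fh.write(json.dumps({
                "frame": i, "file": frame, "action": actions[i],
                "count": int(iset.counts[i]), "objects": _state_meta(iset.states[i]),
            }) + "\n")


def load_sequence_images(seq_dir: str | Path) -> LabeledImageSet:
    """Read back a saved episode's frames and counts (8-bit quantized)."""
    from PIL import Image

    seq = Path(seq_dir)
    images, counts = [], []
    with open(seq / "metadata.jsonl") as fh:
        for line in fh:
            meta = json.loads(line)
            arr = np.asarray(Image.open(seq / meta["file"]), dtype=np.float32) / 255.0
            images.append(arr)
            counts.append(meta["count"])
    return LabeledImageSet(np.stack(images), np.asarray(counts, dtype=int))
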