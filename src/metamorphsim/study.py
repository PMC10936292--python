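"""Repeated-measures suppression study on synthetic participants.

Each participant, per severity condition, receives one random metamorphopsia
template in one randomly chosen eye; a gaze-locked dark spot is then grown
through the protocol's suppression levels (0, 25, 90, 120% of the distortion
extent), and at every level the participant rates perceived grid distortion
and highlighted-word legibility on the 0–5 scales.  The first level at which
the distortion is imperceptible, and the first level at which the spot
itself is noticed, are recorded per trial.  Scores are analyzed
nonparametrically with Pearson's chi-square on the score-by-level
contingency table.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
from scipy.stats import chi2_contingency

from .distortion import DistortionField
from .observer import (
    SyntheticParticipant,
    grid_distortion_metric,
    legibility_metric,
    participant_response,
    reference_thresholds,
)
from .raster import RasterSpec
from .stimuli import (
    GridSpec,
    ReadingSpec,
    TemplateRanges,
    DEFAULT_RANGES,
    random_metamorphopsia,
    render_amsler,
    render_reading_task,
    severity_presets,
)
from .suppression import PROTOCOL_SCALES, make_spot, spot_mask

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "run_protocol",
    "chi_square_analysis",
    "write_trials_csv",
    "read_trials_csv",
    "CSV_COLUMNS",
]

CSV_COLUMNS = (
    "participant_id",
    "eye",
    "condition_id",
    "task",
    "suppression_scale",
    "score",
    "first_imperceptible_scale",
    "first_noticed_scale",
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Study protocol: participants, severity conditions, suppression levels."""

    n_participants: int = 18
    conditions: tuple[TemplateRanges, ...] = tuple(severity_presets())
    suppression_scales: tuple[float, ...] = PROTOCOL_SCALES
    tasks: tuple[str, ...] = ("grid", "reading")
    seed: int = 0
    raster_spec: RasterSpec = RasterSpec(256, 256, 36.0)
    grid_spec: GridSpec = GridSpec()
    reading_spec: ReadingSpec = ReadingSpec(n_words=20, n_highlighted=3, font_px=14)
    score_noise_sd: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be positive, got {self.n_participants!r}")
        scales = tuple(float(s) for s in self.suppression_scales)
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"suppression_scales must be strictly increasing, got {scales!r}")
        object.__setattr__(self, "suppression_scales", scales)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        for t in self.tasks:
            if t not in ("grid", "reading"):
                raise ValueError(f"unknown task {t!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One scored observation of the protocol."""

    participant_id: int
    eye: str
    condition_id: int
    task: str
    suppression_scale: float
    score: int
    first_imperceptible_scale: float | None = None
    first_noticed_scale: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.score, (int, np.integer)) and 0 <= self.score <= 5):
            raise ValueError(f"score must be an integer in 0..5, got {self.score!r}")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.task not in ("grid", "reading"):
            raise ValueError(f"unknown task {self.task!r}")


def run_protocol(config: ProtocolConfig) -> list[TrialRecord]:
    """Run the full repeated-measures protocol; reproducible from config.seed.

    Per participant: a baseline (no-distortion) presentation is checked to
    score 0, then per condition one random template in a randomly chosen eye
    is rated under ascending suppression levels for every task.  Row count is
    ``n_participants × n_conditions × n_scales × n_tasks``.
    """
    rng = np.random.default_rng(config.seed)
    thresholds = reference_thresholds(DEFAULT_RANGES, config.grid_spec, config.raster_spec)
    _, line_mask = render_amsler(config.grid_spec, config.raster_spec)
    records: list[TrialRecord] = []

    for pid in range(config.n_participants):
        participant = SyntheticParticipant(
            score_noise_sd=config.score_noise_sd,
            lapse_rate=config.lapse_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # baseline: both eyes see an undistorted grid
        baseline = grid_distortion_metric(
            DistortionField(()), None, config.raster_spec, config.grid_spec)
        assert baseline == 0.0

        for cid, ranges in enumerate(config.conditions):
            eye = "left" if rng.random() < 0.5 else "right"
            template = random_metamorphopsia(int(rng.integers(0, 2**31 - 1)), ranges, eye=eye)
            reading_spec = ReadingSpec(
                n_words=config.reading_spec.n_words,
                n_highlighted=config.reading_spec.n_highlighted,
                font_px=config.reading_spec.font_px,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _, boxes = render_reading_task(reading_spec, config.raster_spec)

            per_task_scores: dict[str, list[int]] = {t: [] for t in config.tasks}
            first_noticed: float | None = None
            masks = []
            for scale in config.suppression_scales:
                spot = make_spot(template, scale)
                mask = spot_mask(spot, (0.0, 0.0), config.raster_spec)
                masks.append(mask)
                if first_noticed is None and bool((mask & line_mask).any()):
                    first_noticed = scale
                for task in config.tasks:
                    if task == "grid":
                        m = grid_distortion_metric(
                            template, mask, config.raster_spec, config.grid_spec)
                        ref = thresholds.grid_ref_metric
                    else:
                        m = legibility_metric(
                            template, mask, boxes, config.raster_spec,
                            config.grid_spec.pitch_deg)
                        ref = thresholds.legibility_ref_metric
                    per_task_scores[task].append(
                        participant_response(participant, m, ref))

            for task in config.tasks:
                scores = per_task_scores[task]
                first_imp = next(
                    (sc for sc, v in zip(config.suppression_scales, scores) if v == 0),
                    None,
                )
                for scale, score in zip(config.suppression_scales, scores):
                    records.append(TrialRecord(
                        participant_id=pid, eye=eye, condition_id=cid, task=task,
                        suppression_scale=scale, score=int(score),
                        first_imperceptible_scale=first_imp,
                        first_noticed_scale=first_noticed,
                    ))
    return records


def chi_square_analysis(records: list[TrialRecord], task: str = "grid"):
    """Pearson chi-square of score category (0..5) against suppression level.

    Empty score rows and level columns are dropped before the test
    (df = (r−1)(c−1) on the reduced table).  Returns
    ``(statistic, df, p_value, per_level_means)`` where ``per_level_means``
    maps each suppression scale to the arithmetic mean score.
    """
    rows = [r for r in records if r.task == task]
    levels = sorted({r.suppression_scale for r in rows})
    if len(levels) < 2:
        raise ValueError("chi-square analysis needs at least 2 suppression levels")
    table = np.zeros((6, len(levels)), dtype=float)
    for r in rows:
        table[r.score, levels.index(r.suppression_scale)] += 1
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        raise ValueError("degenerate contingency table: no score/level variation")
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    means = {
        lv: float(np.mean([r.score for r in rows if r.suppression_scale == lv]))
        for lv in levels
    }
    return float(stat), int(dof), float(p), means


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_trials_csv(records: list[TrialRecord], path) -> None:
    """Write trial records to CSV with the documented fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            d = asdict(r)
            writer.writerow([_fmt(d[c]) for c in CSV_COLUMNS])


def read_trials_csv(path) -> list[TrialRecord]:
    """Read trial records back; raises with the offending line number."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != list(CSV_COLUMNS):
            raise ValueError(f"line 1: expected header {','.join(CSV_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise ValueError(f"line {lineno}: expected {len(CSV_COLUMNS)} fields, got {len(row)}")
            d = dict(zip(CSV_COLUMNS, row))
            try:
                records.append(TrialRecord(
                    participant_id=int(d["participant_id"]),
                    eye=d["eye"],
                    condition_id=int(d["condition_id"]),
                    task=d["task"],
                    suppression_scale=float(d["suppression_scale"]),
                    score=int(d["score"]),
                    first_imperceptible_scale=(
                        float(d["first_imperceptible_scale"])
                        if d["first_imperceptible_scale"] != "" else None),
                    first_noticed_scale=(
                        float(d["first_noticed_scale"])
                        if d["first_noticed_scale"] != "" else None),
                ))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return records
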