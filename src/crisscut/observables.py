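"""Scission detection, ensemble summaries, and parameter sweeps.

Scission is detected two ways.  The primary, ``half_label``, is exact ground
truth available only in silico: the first time no complex contains growth
slats of both ribbon halves.  The secondary, ``size_drop``, mirrors what one
would read off a plot of complex size over time — the first sample where the
largest complex has lost at least a fraction ``f`` of its running maximum
(default ``f = 0.3``).  Both are reported; the thresholded detector exists
precisely because its threshold is arbitrary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from . import engine
from .model import BuildConfig, ModelSpec, build_scission_model, cross_interface_bonds

__all__ = [
    "ScissionResult",
    "EnsembleSummary",
    "detect_scission",
    "summarize_ensemble",
    "sweep",
    "pick_wobble_layout",
    "SIZE_DROP_FRACTION",
]

#: "sharp decrease" threshold for the size_drop detector
SIZE_DROP_FRACTION = 0.3


@dataclass(frozen=True)
class ScissionResult:
    """Per-replicate scission outcome.

    ``scission_time`` is None when censored (no scission before the stop
    condition).  ``products`` are the growth-slat counts of the two largest
    complexes at the detected scission.  ``size_drop_time`` is the secondary
    detector's estimate (may differ from the primary or be None).
    """

    scission_time: float | None
    detection_method: str  # half_label | size_drop
    products: tuple[int, int] | None
    seed: int
    size_drop_time: float | None = None

    @property
    def censored(self) -> bool:
        return self.scission_time is None

    def comparable_products(self, initial_growth: int, frac: float = 0.25) -> bool:
        """Both products hold at least ``frac`` of the initial growth slats."""
        if self.products is None:
            return False
        return all(p >= frac * initial_growth for p in self.products[:2])


def _size_drop_time(
    samples: Sequence[tuple], fraction: float = SIZE_DROP_FRACTION
) -> float | None:
    running = 0
    for row in samples:
        t, largest = row[0], row[3]
        if largest > running:
            running = largest
        elif running and largest <= (1.0 - fraction) * running:
            return t
    return None


def detect_scission(
    trajectory: engine.Trajectory,
    spec: ModelSpec | None = None,
    *,
    fraction: float = SIZE_DROP_FRACTION,
) -> ScissionResult:
    """Extract the scission time from one trajectory.

    The half-label time is taken as primary whenever the trajectory carries
    half-bridging information (it always does for models built here); the
    size-drop estimate is attached alongside.
    """
    drop_t = _size_drop_time(trajectory.samples, fraction)
    has_half = len(trajectory.samples[0]) >= 5
    if has_half:
        return ScissionResult(
            scission_time=trajectory.scission_time,
            detection_method="half_label",
            products=trajectory.products,
            seed=trajectory.seed,
            size_drop_time=drop_t,
        )
    return ScissionResult(
        scission_time=drop_t,
        detection_method="size_drop",
        products=None,
        seed=trajectory.seed,
        size_drop_time=drop_t,
    )


@dataclass
class EnsembleSummary:
    condition: str
    n: int
    detected: int
    censored: int
    mean_time: float | None
    se: float | None
    mean_norm: float | None = None

    def as_row(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "detected": self.detected,
            "censored": self.censored,
            "mean_time": self.mean_time,
            "se": self.se,
            "mean_norm": self.mean_norm,
        }


def _summary(condition: str, results: Sequence[ScissionResult]) -> EnsembleSummary:
    times = [r.scission_time for r in results if not r.censored]
    n_det = len(times)
    mean = sum(times) / n_det if n_det else None
    if n_det >= 2:
        var = sum((t - mean) ** 2 for t in times) / (n_det - 1)
        se = math.sqrt(var / n_det)
    else:
        se = None
    return EnsembleSummary(
        condition=condition,
        n=len(results),
        detected=n_det,
        censored=len(results) - n_det,
        mean_time=mean,
        se=se,
    )


def summarize_ensemble(
    results: Mapping[str, Sequence[ScissionResult]] | Sequence[ScissionResult],
    normalize_to: str | None = None,
    *,
    condition: str = "default",
) -> pd.DataFrame:
    """Per-condition mean scission time, standard error and censoring.

    ``results`` is either a single result list (labelled ``condition``) or a
    mapping from condition label to result list.  With ``normalize_to``,
    a ``mean_norm`` column divides every mean by the reference condition's
    mean (the reference normalizes to 1.0).  An all-censored condition has
    undefined mean/SE (None in the table) and is flagged by ``censored == n``.
    Means are computed over detected scissions only; censoring is reported,
    never imputed.
    """
    if not isinstance(results, Mapping):
        results = {condition: list(results)}
    summaries = [_summary(cond, res) for cond, res in results.items()]
    if normalize_to is not None:
        ref = next((s for s in summaries if s.condition == normalize_to), None)
        if ref is None or ref.mean_time is None:
            raise ValueError(f"reference condition {normalize_to!r} has no mean")
        for s in summaries:
            s.mean_norm = None if s.mean_time is None else s.mean_time / ref.mean_time
    return pd.DataFrame([s.as_row() for s in summaries])


def detectors_agree_within_one_event(
    trajectory: engine.Trajectory, fraction: float = SIZE_DROP_FRACTION
) -> bool:
    """Whether the half-label and size-drop detectors point at the same or
    adjacent recorded complex-structure change (or both at nothing)."""
    t_half = trajectory.scission_time
    t_drop = _size_drop_time(trajectory.samples, fraction)
    if t_half is None or t_drop is None:
        return t_half is None and t_drop is None
    times = [row[0] for row in trajectory.samples]
    try:
        i_half = times.index(t_half)
        i_drop = times.index(t_drop)
    except ValueError:
        return False
    return abs(i_half - i_drop) <= 1


# ---------------------------------------------------------------------------
# wobble layouts


def pick_wobble_layout(
    spec_or_config: ModelSpec | BuildConfig,
    n: int,
    arrangement: str = "terminal",
) -> tuple[tuple[int, int], ...]:
    """Choose ``n`` cross-interface growth bonds to weaken.

    Only cross-interface bonds are offered: in a growth-free scission
    simulation, wobbles elsewhere cannot change the outcome.  Arrangements:

    ``terminal`` (default)
        the bonds hugging the migration-terminal corner of the interface
        (the deep-interior sites each cut family displaces last), taken
        alternately along the two terminal edges.  A ratchet placed where
        the joint random walk completes prevents re-zipping of the very
        sites that gate scission, which makes this the most effective
        placement in ensemble comparisons (see the methods notes);
    ``front_spread``
        evenly spaced along the toehold-proximal diagonal
        (``j - i = L - 1``), where branch migration initiates;
    ``front_block``
        the first ``n`` contiguous bonds of that diagonal;
    ``uniform``
        evenly spaced over all cross-interface bonds sorted by ``(i, j)``.
    """
    if isinstance(spec_or_config, BuildConfig):
        spec = build_scission_model(spec_or_config)
    else:
        spec = spec_or_config
    L = spec.config.core_slat_length
    cross = []
    for a, b in sorted(cross_interface_bonds(spec)):
        x, y = (a, b) if a.slat.kind == "X" else (b, a)
        cross.append((x.slat.index, y.slat.index))
    cross = sorted(set(cross))
    if arrangement == "terminal":
        half_n = max(i for i, _ in cross)  # deep corner is (N/2, N/2 + 1)
        cross_set = set(cross)
        pool = [(half_n, half_n + 1)]
        for k in range(1, L):
            row = (half_n - k, half_n + 1)  # along the deep y row
            col = (half_n, half_n + 1 + k)  # along the deep x column
            pool.extend(p for p in (row, col) if p in cross_set)
    elif arrangement in ("front_spread", "front_block"):
        pool = [(i, j) for i, j in cross if j - i == L - 1]
    elif arrangement == "uniform":
        pool = cross
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if n > len(pool):
        raise ValueError(f"requested {n} wobbles but only {len(pool)} positions")
    if arrangement in ("terminal", "front_block"):
        return tuple(pool[:n])
    if n == 1:
        return (pool[0],)
    idx = sorted({round(k * (len(pool) - 1) / (n - 1)) for k in range(n)})
    return tuple(pool[i] for i in idx)


# ---------------------------------------------------------------------------
# sweeps


def _condition_label(overrides: Mapping) -> str:
    parts = []
    for k in sorted(overrides):
        v = overrides[k]
        if k == "wobble_layout":
            v = f"{len(v)}w@{'|'.join(f'{i}-{j}' for i, j in v)}"
        parts.append(f"{k}={v}")
    return ",".join(parts) or "base"


def sweep(
    grid: Sequence[Mapping],
    base_config: BuildConfig,
    mode: str,
    n: int,
    base_seed: int,
    *,
    t_max: float = 20000.0,
    normalize_to: str | None = None,
) -> tuple[pd.DataFrame, dict[str, list[ScissionResult]]]:
    """Run an ensemble per grid point and summarize.

    Each grid point is a dict of :class:`BuildConfig` field overrides, plus
    optionally ``"mode"``.  Grid point ``c`` uses replicate seeds
    ``base_seed + 10000 * c + r``, making the whole sweep a pure function of
    ``(grid, base_config, mode, n, base_seed)``.  Invalid grid points are
    recorded as failed conditions (error column) and the sweep continues.
    Output rows follow grid order.
    """
    all_results: dict[str, list[ScissionResult]] = {}
    summaries: dict[str, Sequence[ScissionResult]] = {}
    errors: dict[str, str] = {}
    for c, overrides in enumerate(grid):
        overrides = dict(overrides)
        cond_mode = overrides.pop("mode", mode)
        label_fields = dict(overrides)
        if cond_mode != mode:
            label_fields["mode"] = cond_mode
        label = _condition_label(label_fields)
        try:
            cfg = replace(base_config, **overrides)
            spec = build_scission_model(cfg)
        except Exception as exc:  # invalid grid point: record, continue
            errors[label] = str(exc)
            all_results[label] = []
            continue
        trajs = engine.run_ensemble(
            spec, cond_mode, n, base_seed + 10000 * c, t_max=t_max
        )
        res = [detect_scission(tr, spec) for tr in trajs]
        all_results[label] = res
        summaries[label] = res
    table = summarize_ensemble(summaries, normalize_to) if summaries else pd.DataFrame()
    if errors:
        err_rows = pd.DataFrame(
            [{"condition": label, "error": msg} for label, msg in errors.items()]
        )
        table = pd.concat([table, err_rows], ignore_index=True)
    return table, all_results
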