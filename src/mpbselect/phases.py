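"""Partition of the census years into onset, peak, and collapse phases.

Outbreak phases are defined park-wide from the yearly infested-cell counts:
onset (rising), peak (high plateau), collapse (declining). Explicit year
ranges from configuration are the primary path; an automatic rule based on
the trajectory is provided as a labeled heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PhasePartitionError

PHASE_ORDER = ("onset", "peak", "collapse")


@dataclass(frozen=True)
class PhaseLabel:
    """One phase and its inclusive, contiguous year range."""

    phase: str
    start: int
    end: int

    def __post_init__(self):
        if self.phase not in PHASE_ORDER:
            raise PhasePartitionError(f"unknown phase {self.phase!r}")
        if self.end < self.start:
            raise PhasePartitionError(
                f"{self.phase}: end {self.end} before start {self.start}"
            )

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)


def partition_explicit(years_config: dict[str, tuple[int, int]]) -> list[PhaseLabel]:
    """Validate and return configured phase ranges.

    ``years_config`` maps each of onset/peak/collapse to an inclusive
    (start, end) pair; the three ranges must be ordered, non-overlapping and
    contiguous (each phase starts the year after the previous one ends).
    """
    missing = set(PHASE_ORDER) - set(years_config)
    if missing:
        raise PhasePartitionError(f"missing phase ranges: {sorted(missing)}")
    labels = [PhaseLabel(p, *map(int, years_config[p])) for p in PHASE_ORDER]
    for prev, cur in zip(labels, labels[1:]):
        if cur.start != prev.end + 1:
            raise PhasePartitionError(
                f"{cur.phase} must start the year after {prev.phase} ends "
                f"({prev.end}); got {cur.start}"
            )
    return labels


def partition_auto(
    trajectory: dict[int, float], peak_fraction: float = 0.8
) -> list[PhaseLabel]:
    """Phase partition from the yearly infestation trajectory.

    The peak is the maximal contiguous run of years whose count reaches
    ``peak_fraction`` of the trajectory maximum; onset and collapse are the
    years before and after. Invariant to rescaling all counts by a positive
    constant. Fails if either flank would be empty (monotone trajectories).
    """
    years = sorted(trajectory)
    if len(years) < 3:
        raise PhasePartitionError("need at least three years to partition")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise PhasePartitionError(f"trajectory years are not contiguous: {years}")
    counts = [trajectory[y] for y in years]
    if any(c < 0 for c in counts):
        raise PhasePartitionError("counts must be non-negative")
    peak_level = peak_fraction * max(counts)
    if max(counts) <= 0:
        raise PhasePartitionError("all counts are zero")

    hot = [c >= peak_level for c in counts]
    runs = []
    start = None
    for i, h in enumerate(hot + [False]):
        if h and start is None:
            start = i
        elif not h and start is not None:
            runs.append((start, i - 1))
            start = None
    best = max(runs, key=lambda r: r[1] - r[0])
    i0, i1 = best
    if i0 == 0:
        raise PhasePartitionError("no onset: trajectory already at peak level")
    if i1 == len(years) - 1:
        raise PhasePartitionError("no collapse: trajectory never leaves peak level")
    return [
        PhaseLabel("onset", years[0], years[i0 - 1]),
        PhaseLabel("peak", years[i0], years[i1]),
        PhaseLabel("collapse", years[i1 + 1], years[-1]),
    ]


def phase_years(labels: list[PhaseLabel]) -> dict[str, list[int]]:
    """Convenience map phase name -> list of years."""
    return {lab.phase: list(lab.years) for lab in labels}
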