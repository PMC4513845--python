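"""Run configuration.

A run is defined by the input data plus a :class:`RunConfig` holding the
cluster count ``k``, the per-gene membership multiplicity ``v``, the
iteration budget, the scoring schedule and all numerical constants of the
optimization.  Every parameter has a default chosen to work on compendium-
scale expression data; any of them can be overridden from a ``key=value``
config file or the command line (command line wins over file, file wins
over defaults).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ScheduleEntry:
    """Activation rule for one scoring function.

    ``start:stop:step`` iteration ranges are inclusive of ``start`` and
    ``stop``.  ``start_frac`` expresses the start as a fraction of the run
    so defaults scale with the iteration budget; an explicit ``start`` > 1
    wins.  ``weight`` is the relative weight handed to the combiner; the
    motif scorer additionally ramps its weight up over the run.
    """

    scorer: str
    start: int = 1
    stop: int = 0  # 0 -> run's final iteration
    step: int = 1
    weight: float = 1.0
    start_frac: float | None = None

    def start_at(self, total: int) -> int:
        if self.start > 1 or self.start_frac is None:
            return self.start
        return max(1, round(self.start_frac * total))

    def active(self, iteration: int, total: int) -> bool:
        start = self.start_at(total)
        stop = self.stop if self.stop > 0 else total
        if iteration < start or iteration > stop:
            return False
        return (iteration - start) % self.step == 0


def default_schedule() -> list[ScheduleEntry]:
    # Expression organizes the clusters from the first iteration; the
    # reinforcement scorers join later (motif weight additionally ramps and
    # caps at half the expression weight, and set enrichment waits for the
    # mid-run) so that clusters do not lock onto shared motif/set training
    # signals while the annealing noise is still high.
    return [
        ScheduleEntry("expression", weight=1.0),
        ScheduleEntry("network", weight=0.5),
        # Motif search is expensive: refresh every 100 iterations.
        ScheduleEntry("motif", step=100, weight=0.5, start_frac=0.05),
        ScheduleEntry("sets", weight=1.0, start_frac=0.5),
    ]


@dataclass
class RunConfig:
    k: int | None = None          # cluster count; None -> n_genes * v / 20
    v: int = 2                    # bicluster memberships per gene
    iterations: int = 2000
    rng_seed: int = 1
    schedule: list[ScheduleEntry] = field(default_factory=default_schedule)

    # membership update
    sample_fraction: float = 0.5  # elements considered for a move per iteration
    min_cluster_genes: int = 3
    max_cluster_genes: int = 70

    # combiner / probability model
    noise_sd0: float = 0.25       # initial score noise, standardized units
    kernel_bandwidth_c: float = 20.0
    kernel_max_refs: int = 128    # bin the kernel-CDF reference above this size

    # motif scoring
    motif_backend: str = "internal"   # meme | weeder | internal | none
    motif_n_max: int = 4
    motif_min_width: int = 6
    motif_max_width: int = 8
    motif_ramp_end: float = 2.0 / 3.0  # fraction of run at which weight reaches 1
    motif_n_shuffles: int = 1000

    # set enrichment
    set_alpha: float = 0.05       # alpha for the Bonferroni low-pass floor

    # io policies
    duplicate_row_policy: str = "mean"    # first | mean
    duplicate_edge_policy: str = "max"    # max | sum
    promoter_window: tuple[int, int] = (-250, 50)
    operon_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.v < 1:
            raise ValueError("v must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for entry in self.schedule:
            if entry.weight < 0:
                raise ValueError("schedule weights must be >= 0")

    def scorer_entry(self, scorer: str) -> ScheduleEntry | None:
        for entry in self.schedule:
            if entry.scorer == scorer:
                return entry
        return None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def read_config_file(path: str | Path) -> dict:
    """Parse a ``key=value`` config file into an override dict.

    Schedule entries use dotted keys, e.g. ``scorer.motif.iterations=100:2000:100``
    and ``scorer.network.weight=0.5``.  Comment lines start with ``#``.
    """
    overrides: dict = {}
    schedule: dict[str, dict] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("scorer."):
            _, scorer, attr = key.split(".", 2)
            entry = schedule.setdefault(scorer, {})
            if attr == "iterations":
                parts = [int(x) for x in value.split(":")]
                start, stop, step = (parts + [0, 1])[:3]
                entry.update(start=start, stop=stop, step=step)
            elif attr == "weight":
                entry["weight"] = float(value)
            else:
                raise ValueError(f"unknown scorer attribute {attr!r}")
        else:
            overrides[key] = _coerce(value)
    if schedule:
        overrides["schedule"] = schedule
    return overrides


def build_config(file_overrides: dict | None = None,
                 cli_overrides: dict | None = None) -> RunConfig:
    """Merge defaults < config file < command line into a RunConfig."""
    merged: dict = {}
    schedule_over: dict[str, dict] = {}
    for layer in (file_overrides or {}, cli_overrides or {}):
        for key, value in layer.items():
            if key == "schedule":
                for scorer, attrs in value.items():
                    schedule_over.setdefault(scorer, {}).update(attrs)
            elif value is not None:
                merged[key] = value
    cfg = RunConfig(**merged)
    if schedule_over:
        by_name = {e.scorer: e for e in cfg.schedule}
        for scorer, attrs in schedule_over.items():
            entry = by_name.get(scorer)
            if entry is None:
                entry = ScheduleEntry(scorer)
                cfg.schedule.append(entry)
            for attr, val in attrs.items():
                setattr(entry, attr, val)
    return cfg
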