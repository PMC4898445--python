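"""Plain-text configuration parsing, TSV time series, and genome dumps.

The configuration format is a properties-style ``key=value`` file: blank
lines and ``#`` comments are ignored, unknown keys are rejected, and
missing keys take the model defaults.  Keys are exactly the field names of
:class:`ploidysim.core.SimParams` (``n``, ``g``, ``f0``, ``m``, ``b``,
``k_d``, ``k_b``, ``s``, ``p``, ``p_max``, ``q``, ``d``, ``r_conv``,
``r_cross``, ``r_lgt``, ``r_ex``, ``r_pair``, ``homology``, ``seed``,
``max_generations``, ``ploidy_mode``, ``initial_composition``).  A mixed
initial population is written ``initial_composition=2000:constant,2000:variable``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .core import Cell, Population, SimParams, validate_params
from .engine import RunResult
from .recombination import most_similar_chromosome

__all__ = [
    "ConfigError",
    "read_config",
    "parse_config_text",
    "write_timeseries",
    "timeseries_frame",
    "dump_genomes",
    "parse_genome_dump",
]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration input."""


_INT_KEYS = {"n", "g", "p", "p_max", "max_generations", "seed"}
_FLOAT_KEYS = {
    "f0", "m", "b", "k_d", "k_b", "s", "q", "d",
    "r_conv", "r_cross", "r_lgt", "r_ex", "r_pair",
}
_BOOL_KEYS = {"homology"}
_STR_KEYS = {"ploidy_mode"}


def _parse_bool(raw: str, key: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes", "on"):
        return True
    if low in ("false", "0", "no", "off"):
        return False
    raise ConfigError(f"cannot parse boolean value {raw!r} for key {key!r}")


def _parse_composition(raw: str) -> tuple[tuple[int, str], ...]:
    groups = []
    for part in raw.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            count, mode = part.split(":")
            groups.append((int(count), mode.strip()))
        except ValueError as exc:
            raise ConfigError(
                f"malformed initial_composition group {part!r} (expected COUNT:MODE)"
            ) from exc
    if not groups:
        raise ConfigError("initial_composition is empty")
    return tuple(groups)


def parse_config_text(text: str) -> SimParams:
    """Parse configuration text into validated :class:`SimParams`."""
    values: dict = {}
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"malformed line {lineno}: {raw_line.strip()!r} (expected key=value)")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in _INT_KEYS:
            try:
                values[key] = int(raw)
            except ValueError as exc:
                raise ConfigError(f"cannot parse integer value {raw!r} for key {key!r}") from exc
        elif key in _FLOAT_KEYS:
            try:
                values[key] = float(raw)
            except ValueError as exc:
                raise ConfigError(f"cannot parse numeric value {raw!r} for key {key!r}") from exc
        elif key in _BOOL_KEYS:
            values[key] = _parse_bool(raw, key)
        elif key in _STR_KEYS:
            values[key] = raw
        elif key == "initial_composition":
            values[key] = _parse_composition(raw)
        else:
            raise ConfigError(f"unknown configuration key {key!r} (line {lineno})")
    return validate_params(SimParams(**values))


def read_config(path) -> SimParams:
    """Read and validate a ``key=value`` configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    return parse_config_text(text)


def config_text(params: SimParams) -> str:
    """Render parameters back to configuration text (round-trippable)."""
    lines = []
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if f.name == "initial_composition":
            if v is None:
                continue
            v = ",".join(f"{c}:{m}" for c, m in v)
        elif isinstance(v, bool):
            v = "true" if v else "false"
        lines.append(f"{f.name}={v}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------


def timeseries_frame(result: RunResult):
    """Per-generation statistics of a run as a pandas DataFrame."""
    import pandas as pd

    p_max = max((max(r.ploidy_histogram, default=0) for r in result.records), default=0)
    rows = []
    for r in result.records:
        row = {
            "generation": r.generation,
            "n_alive": r.n_alive,
            "mean_f": r.mean_f,
            "min_f": r.min_f,
            "max_f": r.max_f,
            "mean_ploidy": r.mean_ploidy,
            "monoploid_fraction": r.monoploid_fraction,
        }
        for p in range(1, p_max + 1):
            row[f"n_ploidy_{p}"] = r.ploidy_histogram.get(p, 0)
        for label, count in r.lineage_counts.items():
            row[f"n_{label}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def write_timeseries(result: RunResult, path) -> None:
    """Write the run's per-generation statistics as a TSV file."""
    frame = timeseries_frame(result)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome dumps
# ---------------------------------------------------------------------------


def _similarity_order(genes: np.ndarray) -> list[int]:
    """Greedy nearest-neighbour chaining on identical-gene counts."""
    remaining = list(range(genes.shape[0]))
    order = [remaining.pop(0)]
    while remaining:
        last = genes[order[-1]]
        matches = [(genes[i] == last).sum() for i in remaining]
        best = int(np.argmax(matches))
        order.append(remaining.pop(best))
    return order


def dump_genomes(pop: Population, k: int, ordering: str = "similarity") -> str:
    """TSV dump of the genomes of the first ``k`` cells.

    One row per chromosome: cell id, chromosome rank, then the gene values
    at full precision.  ``ordering='similarity'`` sorts each cell's
    chromosomes by greedy nearest-neighbour chaining so near-identical
    copies are adjacent (as one would lay them out for inspection);
    ``'native'`` keeps storage order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ordering not in ("similarity", "native"):
        raise ValueError(f"unknown ordering {ordering!r}")
    g = pop.n_genes
    header = ["cell", "chromosome"] + [f"gene_{i}" for i in range(g)]
    lines = ["\t".join(header)]
    for ci in range(min(k, pop.n_cells)):
        genes = pop.cell_genes(ci)
        order = _similarity_order(genes) if ordering == "similarity" else list(range(len(genes)))
        for rank, row in enumerate(order):
            vals = "\t".join(repr(float(v)) for v in genes[row])
            lines.append(f"{ci}\t{rank}\t{vals}")
    return "\n".join(lines) + "\n"


def parse_genome_dump(text: str) -> list[Cell]:
    """Re-parse a genome dump into cells (gene values exact)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    body = lines[1:]
    by_cell: dict[int, list[list[float]]] = {}
    for ln in body:
        parts = ln.split("\t")
        cell_id = int(parts[0])
        by_cell.setdefault(cell_id, []).append([float(v) for v in parts[2:]])
    return [Cell(np.array(rows)) for _, rows in sorted(by_cell.items())]
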