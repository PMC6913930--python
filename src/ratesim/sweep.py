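"""Parameter grid search as one stacked, edge-free vectorized run.

Instead of looping over parametrizations, :func:`grid_search` instantiates
every grid point as a sub-circuit of one stacked circuit *without any edges
between instances*, compiles the stack with vectorization enabled (all
instances of a node collapse into one vectorized node with per-instance
constants), and integrates everything in a single run.  Results carry a
stable grid-point identifier per column plus a parameter table.

Grid keys address either operator constants by variable path
(``PC/RPO_e/tau``, sub-circuit prefixes included) or, as the special bare
keys ``weight`` / ``delay``, the swept template's own top-level edges —
e.g. the inter-circuit coupling strength and propagation delay of a
two-column model.  Expansion order is the cartesian product, lexicographic
over parameter names and row-major over value lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .engine import CompiledNetwork, EngineError, SimulationResult, compile as compile_network
from .templates import CircuitTemplate

__all__ = ["ParameterGrid", "GridSearchResult", "grid_search", "run_points"]

_EDGE_KEYS = ("weight", "delay")


@dataclass
class ParameterGrid:
    """Cartesian parameter grid with stable point identifiers.

    ``axes`` maps a parameter key to its value list.  The expansion is the
    cartesian product with parameter names in lexicographic order and the
    last axis varying fastest; point ``k`` gets identifier ``p{k}``.
    """

    axes: Dict[str, Sequence[float]]

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("parameter grid must define at least one axis")
        self.axes = {str(k): list(v) for k, v in self.axes.items()}
        for key, values in self.axes.items():
            if len(values) == 0:
                raise ValueError(f"axis {key!r} has no values")

    def __len__(self) -> int:
        n = 1
        for values in self.axes.values():
            n *= len(values)
        return n

    def points(self) -> List[Tuple[str, Dict[str, float]]]:
        keys = sorted(self.axes)
        combos = itertools.product(*[self.axes[k] for k in keys])
        return [(f"p{i}", dict(zip(keys, combo)))
                for i, combo in enumerate(combos)]

    def table(self) -> pd.DataFrame:
        ids, rows = zip(*self.points())
        return pd.DataFrame(list(rows), index=pd.Index(ids, name="point"))


@dataclass
class GridSearchResult:
    """Stacked-run results: one column set per grid point.

    ``data`` columns are a MultiIndex (point, output, node); ``params`` is
    the per-point parameter table.
    """

    data: pd.DataFrame
    params: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    @property
    def point_ids(self) -> List[str]:
        return list(self.params.index)

    def series(self, point: str, output: str) -> np.ndarray:
        values = self.data[point][output].to_numpy()
        return values[:, 0] if values.shape[1] == 1 else values

    def to_csv(self, path: str) -> None:
        flat = self.data.copy()
        flat.columns = ["/".join(c).rstrip("/") for c in flat.columns]
        flat.to_csv(path)


def _stacked_template(template: CircuitTemplate,
                      points: Sequence[Tuple[str, Mapping[str, float]]],
                      ) -> Tuple[CircuitTemplate, Dict[str, float]]:
    circuits: Dict[str, CircuitTemplate] = {}
    values: Dict[str, float] = {}
    for pid, overrides in points:
        edge_kwargs = {k: overrides[k] for k in _EDGE_KEYS if k in overrides}
        instance = template.with_edge_attrs(**edge_kwargs) if edge_kwargs \
            else template
        circuits[pid] = instance
        for key, value in overrides.items():
            if key in _EDGE_KEYS:
                continue
            values[f"{pid}/{key}"] = float(value)
    stacked = CircuitTemplate(name=f"{template.name}_grid", nodes={},
                              circuits=circuits, edges=[])
    return stacked, values


def run_points(template: CircuitTemplate,
               points: Sequence[Tuple[str, Mapping[str, float]]],
               simulation_time: float,
               dt: float = 1e-4,
               solver: str = "euler",
               inputs: Optional[Mapping[str, np.ndarray]] = None,
               outputs: Optional[Mapping[str, str]] = None,
               sampling_step_size: Optional[float] = None,
               vectorization: bool = True,
               ) -> pd.DataFrame:
    """Simulate explicit (id, overrides) points in one stacked run.

    Lower-level sibling of :func:`grid_search` for non-cartesian point sets
    (e.g. parameters linked by a constraint).  Relative input paths
    broadcast to every instance; outputs are re-keyed by point identifier.
    """
    stacked, values = _stacked_template(template, points)
    circuit = stacked.apply(values)
    network = compile_network(circuit, dt=dt, solver=solver,
                              vectorization=vectorization)
    result = network.run(simulation_time, inputs=inputs, outputs=outputs,
                         sampling_step_size=sampling_step_size)
    columns = {}
    for (name, node_path), series in result.df.items():
        pid, _, rest = node_path.partition("/")
        columns[(pid, name, rest)] = series.to_numpy()
    df = pd.DataFrame(columns, index=result.df.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["point", "output", "node"])
    return df.sort_index(axis=1, key=_point_sort_key)


def _point_sort_key(index):
    if index.name == "point":
        return index.map(lambda p: int(p[1:]) if p[1:].isdigit() else p)
    return index


def grid_search(template: CircuitTemplate,
                grid: Union[ParameterGrid, Mapping[str, Sequence[float]]],
                simulation_time: float,
                dt: float = 1e-4,
                solver: str = "euler",
                inputs: Optional[Mapping[str, np.ndarray]] = None,
                outputs: Optional[Mapping[str, str]] = None,
                sampling_step_size: Optional[float] = None,
                vectorization: bool = True,
                max_instances: int = 20000,
                chunk_size: Optional[int] = None,
                ) -> GridSearchResult:
    """Cartesian parameter sweep executed as stacked vectorized runs.

    Builds one circuit containing ``len(grid)`` template instances with no
    edges between them and simulates them together; extrinsic inputs with
    relative paths are broadcast to every instance.  ``chunk_size`` splits
    the grid into sequentially executed stacked chunks (bounding memory,
    and standing in for distribution across machines); the merged table is
    identical either way.  ``max_instances`` guards against accidental
    memory blow-up (instances = grid points x nodes per template).
    """
    if not isinstance(grid, ParameterGrid):
        grid = ParameterGrid(dict(grid))
    points = grid.points()
    n_nodes = len(template.apply().flatten().nodes)
    if len(points) * n_nodes > max_instances:
        raise EngineError(
            f"grid of {len(points)} points x {n_nodes} nodes exceeds "
            f"max_instances={max_instances}; raise the guard or chunk the "
            "grid")
    chunks: List[Sequence[Tuple[str, Dict[str, float]]]]
    if chunk_size is None or chunk_size >= len(points):
        chunks = [points]
    else:
        chunks = [points[i:i + chunk_size]
                  for i in range(0, len(points), chunk_size)]
    frames = [run_points(template, chunk, simulation_time, dt=dt,
                         solver=solver, inputs=inputs, outputs=outputs,
                         sampling_step_size=sampling_step_size,
                         vectorization=vectorization)
              for chunk in chunks]
    data = frames[0] if len(frames) == 1 else pd.concat(frames, axis=1)
    metadata = {"dt": dt, "solver": solver,
                "simulation_time": simulation_time,
                "n_points": len(points), "chunks": len(chunks)}
    return GridSearchResult(data, grid.table(), metadata)
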