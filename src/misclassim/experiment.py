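"""The crossed Monte Carlo design: run every method over every cell and
replication, collect per-replication misclassification rates, and reduce the
results to marginal tables by design factor.

The full default grid crosses 2 topologies x 2 sample sizes x 4 group-size
ratios x 4 separations x 4 mislabeling proportions (256 cells); each
(cell, replication) pair gets its own reproducible random stream derived from
the master seed, and a further derived stream feeds classifier-internal
randomness, so runs are deterministic and resumable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import classifiers as clf
from .metrics import misclassification_rates
from .simulate import SimCondition, Topology, simulate_condition

logger = logging.getLogger(__name__)

__all__ = ["DesignGrid", "run_design", "marginal_table", "RESULT_COLUMNS"]

RESULT_COLUMNS = ["method", "topology", "n_total", "ratio", "d", "pi", "rep",
                  "overall", "g1", "g2", "g3"]

_DEFAULT_RATIOS = ((50, 50, 50), (25, 25, 100), (25, 100, 25), (100, 25, 25))


@dataclass(frozen=True)
class DesignGrid:
    """Factor levels of the crossed design plus replication count and seed."""

    topologies: tuple[str, ...] = ("BC", "AB_BC")
    n_totals: tuple[int, ...] = (150, 1500)
    ratios: tuple[tuple[int, int, int], ...] = _DEFAULT_RATIOS
    separations: tuple[float, ...] = (0.2, 0.5, 0.8, 1.6)
    pis: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
    replications: int = 1000
    master_seed: int = 0
    eligibility_mode: str = "strict"

    def __post_init__(self) -> None:
        if any(len(r) != 3 for r in self.ratios):
            raise ValueError("every ratio needs three entries")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.eligibility_mode not in ("strict", "uniform"):
            raise ValueError(f"unknown eligibility_mode {self.eligibility_mode!r}")
        for name in self.topologies:
            Topology.from_name(name)  # validates

    @property
    def n_cells(self) -> int:
        return (len(self.topologies) * len(self.n_totals) * len(self.ratios)
                * len(self.separations) * len(self.pis))

    def cells(self) -> Iterable[tuple[int, dict]]:
        for idx, (topo, n, ratio, d, pi) in enumerate(product(
                self.topologies, self.n_totals, self.ratios,
                self.separations, self.pis)):
            yield idx, {"topology": topo, "n_total": n, "ratio": ratio,
                        "d": d, "pi": pi}

    def condition(self, cell_index: int, cell: dict, rep: int) -> SimCondition:
        """The simulation condition for one (cell, replication) pair.

        The seed is the tuple (master, cell, rep) fed to a SeedSequence, so
        any cell/replication can be re-simulated in isolation.
        """
        return SimCondition(
            topology=Topology.from_name(cell["topology"], self.eligibility_mode),
            n_total=cell["n_total"], ratio=tuple(cell["ratio"]),
            separation_d=cell["d"], pi=cell["pi"],
            seed=np.random.SeedSequence((self.master_seed, cell_index, rep)))


def _ratio_str(ratio) -> str:
    return ":".join(str(int(r)) for r in ratio)


def run_design(grid: DesignGrid, methods: Sequence[str] = clf.METHOD_NAMES,
               settings: dict | None = None, reference: str = "true",
               cell_filter=None) -> pd.DataFrame:
    """Run the crossed design and return the long results table.

    One row per (method, cell, replication) holding the overall and per-group
    misclassification rates of resubstitution predictions, scored against the
    ``reference`` labels ("true" by default, "observed" optionally).  A
    degenerate fit (e.g. an observed class collapsing to a single case) is
    logged and skipped rather than aborting the run.

    ``cell_filter`` (cell dict -> bool) restricts the grid, e.g. to one
    topology or one mislabeling proportion.
    """
    unknown = set(m.upper() for m in methods) - set(clf.METHOD_NAMES)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if reference not in ("true", "observed"):
        raise ValueError("reference must be 'true' or 'observed'")
    methods = [m.upper() for m in methods]
    rows = []
    for cell_index, cell in grid.cells():
        if cell_filter is not None and not cell_filter(cell):
            continue
        for rep in range(grid.replications):
            cond = grid.condition(cell_index, cell, rep)
            ds = simulate_condition(cond)
            ref = ds.true_label if reference == "true" else ds.observed_label
            X = ds.x[:, None]
            # independent stream for classifier-internal randomness
            clf_seed = np.random.SeedSequence(
                (grid.master_seed, cell_index, rep, 1))
            for method in methods:
                model = clf.make_classifier(method, settings, clf_seed)
                try:
                    model.fit(X, ds.observed_label)
                except clf.DegenerateFitError as exc:
                    logger.warning("degenerate %s fit in cell %s rep %d: %s",
                                   method, cell, rep, exc)
                    continue
                rec = misclassification_rates(model.predict(X), ref)
                rows.append((method, cell["topology"], cell["n_total"],
                             _ratio_str(cell["ratio"]), cell["d"], cell["pi"],
                             rep, rec.overall, *rec.group_rates))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def marginal_table(results: pd.DataFrame, factor: str,
                   cell_filter: str | None = None) -> pd.DataFrame:
    """Mean rates per (factor level, method) over all retained rows.

    ``factor`` is one of pi, ratio, d, n_total, method; ``cell_filter`` is an
    optional pandas query string (e.g. ``"topology == 'AB_BC'"``).  With the
    balanced design these simple means are the design marginals.
    """
    valid = {"pi", "ratio", "d", "n_total", "method"}
    if factor not in valid:
        raise ValueError(f"factor must be one of {sorted(valid)}")
    df = results.query(cell_filter) if cell_filter else results
    if df.empty:
        raise ValueError("no rows retained by the filter")
    keys = [factor] if factor == "method" else [factor, "method"]
    out = (df.groupby(keys, sort=True)[["overall", "g1", "g2", "g3"]]
             .mean().reset_index())
    return out
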