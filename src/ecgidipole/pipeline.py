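"""Two-step inverse solution: full-montage localization, electrode ranking at
the estimated origin, and re-localization with nested significant subsets.

Step one scans all candidate positions with every electrode and keeps the
global RRE minimum. Step two ranks the electrodes by significance for the
transfer matrix of that winning position (per criterion), then re-solves the
inverse problem using only the k most significant electrodes for a range of
k, recording the localization error of each reduced solution when the true
origin is known. The working assumption is that electrode significance
changes slowly with source position, so a ranking computed at the first-step
estimate remains informative for the true origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .bem import TransferStack
from .inverse import BSPMap, DipoleSolution, localization_error, rre_surface, scan_positions
from .significance import Criterion, greedy_order

__all__ = ["PipelineResult", "run_two_step", "summarize_le"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything the two-step solution produces for one map.

    ``le_by_k[criterion][k]`` is the localization error using the k most
    significant electrodes; ``flatness_by_k`` carries the RRE-surface
    flatness diagnostic (5th-percentile over median of per-position best RRE;
    close to 1 means no identifiable minimum, typical of very small k).
    """

    first_solution: DipoleSolution
    orders: dict
    positions_by_k: dict
    le_all: float | None
    le_by_k: dict
    deltas: dict
    flatness_by_k: dict
    k_values: tuple

    def to_dict(self) -> dict:
        d = {
            "first_solution": self.first_solution.to_dict(),
            "le_all_mm": self.le_all,
            "k_values": list(self.k_values),
            "orders": {c: [int(i) for i in o.order] for c, o in self.orders.items()},
            "le_by_k": {
                c: {str(k): v for k, v in table.items()} for c, table in self.le_by_k.items()
            },
            "deltas": {c: {str(k): v for k, v in t.items()} for c, t in self.deltas.items()},
            "flatness_by_k": {
                c: {str(k): v for k, v in t.items()} for c, t in self.flatness_by_k.items()
            },
            "positions_by_k": {
                c: {str(k): [float(x) for x in p] for k, p in t.items()}
                for c, t in self.positions_by_k.items()
            },
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def run_two_step(
    stack: TransferStack,
    bsp: BSPMap,
    criteria=(Criterion.A, Criterion.B, Criterion.C),
    truth=None,
    k_values=None,
    seed_searches: dict | None = None,
) -> PipelineResult:
    """Run the full two-step inverse solution.

    Parameters
    ----------
    stack, bsp : transfer stack and measured map sharing M electrodes.
    criteria : significance criteria to rank with (default all three).
    truth : optional true origin (mm); enables localization errors.
    k_values : electrode counts for the second step. Defaults to every k in
        [4, M]; pass a shorter list (e.g. ``[32, 64, M]``) to trim work.
    seed_searches : optional pre-computed exhaustive quadruple searches keyed
        by criterion value, reused instead of re-enumerating.

    The second step re-scans the full candidate set restricted to the top-k
    electrode rows; reduced maps and transfer rows are re-referenced to zero
    mean over the retained subset inside the fitting routines.
    """
    criteria = [c if isinstance(c, Criterion) else Criterion(str(c).upper()) for c in criteria]
    if not criteria:
        raise ValueError("at least one criterion required")
    m = stack.n_electrodes
    first = scan_positions(stack, bsp)
    le_all = None if truth is None else localization_error(first.position, truth)

    if k_values is None:
        k_values = tuple(range(4, m + 1))
    else:
        k_values = tuple(int(k) for k in k_values)
        if any(k < 4 or k > m for k in k_values):
            raise ValueError(f"k values must lie in [4, {m}]")

    block_star = stack.blocks[first.position_index]
    orders, le_by_k, deltas, flat_by_k, pos_by_k = {}, {}, {}, {}, {}
    for crit in criteria:
        seed = (seed_searches or {}).get(crit.value)
        order = greedy_order(block_star, crit, seed_search=seed)
        orders[crit.value] = order
        le_tab, d_tab, f_tab, p_tab = {}, {}, {}, {}
        for k in k_values:
            rows = order.top(k)
            sub_stack = stack.subset_electrodes(rows)
            sub_map = bsp.subset(rows)
            sol = scan_positions(sub_stack, sub_map)
            surf = rre_surface(sub_stack, sub_map)
            f_tab[k] = float(np.percentile(surf, 5) / np.median(surf))
            p_tab[k] = sol.position
            if truth is not None:
                le = localization_error(sol.position, truth)
                le_tab[k] = le
                d_tab[k] = le - le_all
        le_by_k[crit.value] = le_tab
        deltas[crit.value] = d_tab
        flat_by_k[crit.value] = f_tab
        pos_by_k[crit.value] = p_tab

    return PipelineResult(
        first_solution=first,
        orders=orders,
        positions_by_k=pos_by_k,
        le_all=le_all,
        le_by_k=le_by_k,
        deltas=deltas,
        flatness_by_k=flat_by_k,
        k_values=k_values,
    )


def summarize_le(results, k_values, tol: float = 1e-9):
    """Cohort summary of second-step localization errors.

    For every criterion and electrode count k: mean and standard deviation of
    LE, mean delta against the full-montage solution, and counts of cases
    that improved (delta < -tol), worsened (delta > tol) or were unchanged.
    Returns a pandas DataFrame with one row per (criterion, k).
    """
    import pandas as pd

    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    if any(r.le_all is None for r in results):
        raise ValueError("all results must carry truth-based localization errors")
    crits = sorted({c for r in results for c in r.le_by_k})
    rows = []
    for c in crits:
        for k in k_values:
            les = np.array([r.le_by_k[c][k] for r in results])
            dl = np.array([r.deltas[c][k] for r in results])
            rows.append(
                {
                    "criterion": c,
                    "k": int(k),
                    "n": len(results),
                    "le_mean_mm": float(les.mean()),
                    "le_sd_mm": float(les.std(ddof=1)) if len(les) > 1 else 0.0,
                    "delta_mean_mm": float(dl.mean()),
                    "improved": int(np.sum(dl < -tol)),
                    "worsened": int(np.sum(dl > tol)),
                    "unchanged": int(np.sum(np.abs(dl) <= tol)),
                }
            )
    return pd.DataFrame(rows)
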