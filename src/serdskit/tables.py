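"""Published reference confusion matrices for the pollen case study.

The pollen SERDS study reports three confusion matrices -- tree vs
non-tree growth habit, tree genera, and non-tree genera -- together with
per-class sensitivity, specificity, accuracy and precision rounded to one
decimal.  They are shipped here as plain data so the metric implementation
can be validated against independently printed numbers: recomputing the
metrics from the printed counts must reproduce the printed percentages to
within rounding (0.05 points).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .classify import METRIC_NAMES, ConfusionMatrix, class_metrics

__all__ = ["PrintedTable", "PRINTED_TABLES", "evaluate_against_printed_tables"]


@dataclass(frozen=True)
class PrintedTable:
    name: str
    class_labels: tuple
    counts: tuple  # rows = predicted, columns = real
    printed_metrics: dict  # metric -> tuple of per-class percentages (1 dp)

    def confusion(self) -> ConfusionMatrix:
        return ConfusionMatrix(counts=np.asarray(self.counts), class_labels=list(self.class_labels))


PRINTED_TABLES: Dict[str, PrintedTable] = {
    "habit": PrintedTable(
        name="habit",
        class_labels=("non_tree", "tree"),
        counts=((2700, 133), (86, 2371)),
        printed_metrics={
            "sensitivity": (96.9, 94.7),
            "specificity": (94.7, 96.9),
            "accuracy": (95.9, 95.9),
            "precision": (95.3, 96.5),
        },
    ),
    "tree_genus": PrintedTable(
        name="tree_genus",
        class_labels=("alder", "hazel", "larch", "birch"),
        counts=(
            (947, 107, 0, 19),
            (54, 696, 2, 16),
            (3, 2, 59, 0),
            (52, 14, 0, 533),
        ),
        printed_metrics={
            "sensitivity": (89.7, 85.0, 96.7, 93.8),
            "specificity": (91.3, 95.7, 99.8, 96.6),
            "accuracy": (90.6, 92.2, 99.7, 96.0),
            "precision": (88.3, 90.6, 92.2, 89.0),
        },
    ),
    "nontree_genus": PrintedTable(
        name="nontree_genus",
        class_labels=("cyclamen", "rumex", "mugwort", "moor_grass"),
        counts=(
            (897, 0, 18, 0),
            (0, 267, 16, 168),
            (16, 0, 676, 0),
            (0, 96, 10, 622),
        ),
        printed_metrics={
            "sensitivity": (98.2, 73.6, 93.9, 78.7),
            "specificity": (99.0, 92.4, 99.2, 94.7),
            "accuracy": (98.8, 89.9, 97.8, 90.2),
            "precision": (98.0, 59.2, 97.7, 85.4),
        },
    ),
}


def evaluate_against_printed_tables(tables: Dict[str, PrintedTable] = PRINTED_TABLES
                                    ) -> pd.DataFrame:
    """Recompute every metric from the printed counts and compare.

    Returns a long table with one row per (table, class, metric):
    recomputed (unrounded) value, printed value, and absolute deviation.
    """
    rows: List[dict] = []
    for table in tables.values():
        recomputed = class_metrics(table.confusion())
        for metric in METRIC_NAMES:
            printed = table.printed_metrics[metric]
            for cls, printed_value in zip(table.class_labels, printed):
                value = float(recomputed.loc[cls, metric])
                rows.append({
                    "table": table.name,
                    "class": cls,
                    "metric": metric,
                    "recomputed": value,
                    "printed": printed_value,
                    "abs_deviation": abs(value - printed_value),
                })
    return pd.DataFrame(rows)
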