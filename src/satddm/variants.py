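"""The seven constraint variants of the model and their DIC ranking.

Each variant fixes which of {a, v, Ter} may differ between the speed and
accuracy instruction conditions; the seven variants are the non-empty
subsets of {a, v, Ter}. Model 1 frees all three; model 3 frees a and Ter
(v invariant); model 6 frees only v. The remaining labels are assigned to
the remaining subsets in a fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["VariantSpec", "enumerate_variants", "compare_models"]


@dataclass(frozen=True)
class VariantSpec:
    free_a: bool
    free_v: bool
    free_ter: bool
    label: str

    def __post_init__(self):
        if not (self.free_a or self.free_v or self.free_ter):
            raise ValueError(
                "at least one of a, v, Ter must vary between conditions")

    @property
    def free_params(self):
        return tuple(p for p, f in (("a", self.free_a), ("v", self.free_v),
                                    ("ter", self.free_ter)) if f)


# label -> (free_a, free_v, free_ter); 1, 3 and 6 are pinned by the reported
# ranking (best / second-best / worst); the rest follow a fixed convention:
# two-parameter variants then single-parameter variants.
_VARIANTS = {
    "model 1": (True, True, True),
    "model 2": (True, True, False),
    "model 3": (True, False, True),
    "model 4": (False, True, True),
    "model 5": (True, False, False),
    "model 6": (False, True, False),
    "model 7": (False, False, True),
}


def enumerate_variants() -> list[VariantSpec]:
    """All seven variants, model 1 (all free) first."""
    return [VariantSpec(*flags, label=lbl) for lbl, flags in _VARIANTS.items()]


def get_variant(label: str) -> VariantSpec:
    if label not in _VARIANTS:
        raise KeyError(f"unknown variant label {label!r}; "
                       f"expected one of {list(_VARIANTS)}")
    return VariantSpec(*_VARIANTS[label], label=label)


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted variants by DIC (ascending), with delta-DIC to the best.

    `fits` is a sequence of dicts with at least {"variant": VariantSpec,
    "dic": float}; extra keys (pD, mean_deviance) are carried through.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    labels = [f["variant"].label for f in fits]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate variant labels in comparison")
    rows = []
    for f in fits:
        var = f["variant"]
        row = {"label": var.label, "free_a": var.free_a, "free_v": var.free_v,
               "free_ter": var.free_ter, "dic": float(f["dic"])}
        for k in ("pD", "mean_deviance"):
            if k in f:
                row[k] = float(f[k])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("dic", kind="mergesort")
    df["delta_dic"] = df["dic"] - df["dic"].min()
    df["best"] = df["delta_dic"] == 0.0
    return df.reset_index(drop=True)
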