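"""TFEQ-R18 subscale scoring.

The shortened Three-Factor Eating Questionnaire (TFEQ-R18) measures three
eating-behavior constructs: cognitive restraint (CR, 6 items), uncontrolled
eating (UE, 9 items), and emotional eating (EE, 3 items).  Raw subscale sums
are rescaled to 0–100 via

    score = (raw - min_possible) / (max_possible - min_possible) * 100

which is invariant to the per-item response range.  UE and EE are commonly
highly correlated; a *disinhibited eating* composite is formed as their mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

SUBSCALES = ("cr", "ue", "ee")

# Standard published TFEQ-R18 item-to-subscale assignment (items numbered 1-18).
_DEFAULT_ASSIGNMENT: dict[str, tuple[int, ...]] = {
    "cr": (2, 11, 12, 15, 16, 18),
    "ue": (1, 4, 5, 7, 8, 9, 13, 14, 17),
    "ee": (3, 6, 10),
}


class TFEQValidationError(ValueError):
    """Raised when item responses violate the declared response ranges."""


@dataclass(frozen=True)
class TFEQItemMap:
    """Item-to-subscale assignment with per-item response ranges and keying.

    Parameters
    ----------
    assignment
        Mapping from subscale label ("cr", "ue", "ee") to 1-based item numbers.
        Subscales must be disjoint and jointly cover items 1..n_items.
    ranges
        Mapping from item number to (min, max) response values. Defaults to
        (1, 4) for every item.
    reverse
        Item numbers whose responses are reverse-keyed (flipped within their
        range before summation).
    """

    assignment: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ASSIGNMENT)
    )
    ranges: dict[int, tuple[int, int]] = field(default_factory=dict)
    reverse: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        items = sorted(i for sub in self.assignment.values() for i in sub)
        n = len(items)
        if items != list(range(1, n + 1)):
            raise ValueError(
                "subscales must be disjoint and cover items 1..n exactly; "
                f"got {items}"
            )
        full = {i: self.ranges.get(i, (1, 4)) for i in items}
        for i, (lo, hi) in full.items():
            if not lo < hi:
                raise ValueError(f"item {i}: range min {lo} must be < max {hi}")
        object.__setattr__(self, "ranges", full)
        object.__setattr__(self, "reverse", frozenset(self.reverse))
        unknown = self.reverse - set(items)
        if unknown:
            raise ValueError(f"reverse-keyed items not in assignment: {sorted(unknown)}")

    @property
    def n_items(self) -> int:
        return sum(len(v) for v in self.assignment.values())

    def items_for(self, subscale: str) -> tuple[int, ...]:
        try:
            return self.assignment[subscale]
        except KeyError:
            raise KeyError(
                f"unknown subscale {subscale!r}; expected one of {sorted(self.assignment)}"
            ) from None

    @classmethod
    def from_yaml(cls, path) -> "TFEQItemMap":
        """Load an item map from a YAML config file.

        Expected keys: ``assignment`` (subscale -> list of item numbers),
        optional ``ranges`` (item -> [min, max]) and ``reverse`` (list).
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        assignment = {k: tuple(v) for k, v in cfg["assignment"].items()}
        ranges = {int(k): tuple(v) for k, v in cfg.get("ranges", {}).items()}
        reverse = frozenset(cfg.get("reverse", []))
        return cls(assignment=assignment, ranges=ranges, reverse=reverse)


def _validate_responses(
    responses: dict[int, float],
    item_map: TFEQItemMap,
    items: tuple[int, ...],
    participant=None,
    prorate: bool = False,
) -> dict[int, float]:
    """Check range constraints; optionally prorate missing items by the mean."""
    who = f" (participant {participant})" if participant is not None else ""
    present: dict[int, float] = {}
    for i in items:
        v = responses.get(i)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        lo, hi = item_map.ranges[i]
        if not lo <= v <= hi:
            raise TFEQValidationError(
                f"item {i} response {v} outside declared range [{lo}, {hi}]{who}"
            )
        present[i] = float(v)
    missing = [i for i in items if i not in present]
    if missing:
        if not prorate or not present:
            raise TFEQValidationError(f"missing responses for items {missing}{who}")
        # prorate: substitute the mean of the answered items, rescaled per item
        mean_frac = np.mean(
            [
                (present[i] - item_map.ranges[i][0])
                / (item_map.ranges[i][1] - item_map.ranges[i][0])
                for i in present
            ]
        )
        for i in missing:
            lo, hi = item_map.ranges[i]
            present[i] = lo + mean_frac * (hi - lo)
    return present


def score_subscale(
    responses,
    item_map: TFEQItemMap | None = None,
    subscale: str = "cr",
    *,
    participant=None,
    prorate_missing: bool = False,
) -> float:
    """Score one TFEQ-R18 subscale on the 0–100 scale.

    Parameters
    ----------
    responses
        Either a mapping {item_number: response} or a sequence of the 18
        responses in item order (index 0 = item 1).
    item_map
        Item assignment, ranges and keying; defaults to the standard map
        with all items on 1–4.
    subscale
        One of "cr", "ue", "ee".
    prorate_missing
        If True, missing items are imputed with the mean response fraction of
        the answered items in the subscale; off by default, in which case a
        missing item raises :class:`TFEQValidationError`.

    Returns
    -------
    float
        ``(raw - min_possible) / (max_possible - min_possible) * 100``, with
        reverse-keyed items flipped before summation.
    """
    if item_map is None:
        item_map = TFEQItemMap()
    if not isinstance(responses, dict):
        seq = list(responses)
        responses = {i + 1: v for i, v in enumerate(seq)}
    items = item_map.items_for(subscale)
    vals = _validate_responses(responses, item_map, items, participant, prorate_missing)
    raw = 0.0
    lo_sum = 0.0
    hi_sum = 0.0
    for i in items:
        lo, hi = item_map.ranges[i]
        v = vals[i]
        if i in item_map.reverse:
            v = lo + hi - v
        raw += v
        lo_sum += lo
        hi_sum += hi
    return (raw - lo_sum) / (hi_sum - lo_sum) * 100.0


def disinhibited_composite(ue: float, ee: float) -> float:
    """Mean of the uncontrolled-eating and emotional-eating 0–100 scores."""
    for name, v in (("ue", ue), ("ee", ee)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} score {v} outside [0, 100]")
    return (ue + ee) / 2.0


def score_tfeq(
    items: pd.DataFrame,
    item_map: TFEQItemMap | None = None,
    *,
    prorate_missing: bool = False,
) -> pd.DataFrame:
    """Score a table of TFEQ-R18 item responses.

    Parameters
    ----------
    items
        One row per participant with a ``participant_id`` column and item
        columns named ``item_1`` .. ``item_18`` (or bare integers 1..18).

    Returns
    -------
    DataFrame with columns participant_id, cr, ue, ee, disinhibited.
    """
    if item_map is None:
        item_map = TFEQItemMap()
    cols = _item_columns(items, item_map.n_items)
    out = []
    for _, row in items.iterrows():
        pid = row["participant_id"]
        resp = {i: row[c] for i, c in cols.items()}
        scores = {
            s: score_subscale(
                resp, item_map, s, participant=pid, prorate_missing=prorate_missing
            )
            for s in item_map.assignment
        }
        scores["disinhibited"] = disinhibited_composite(scores["ue"], scores["ee"])
        out.append({"participant_id": pid, **scores})
    return pd.DataFrame(out)


def _item_columns(items: pd.DataFrame, n_items: int) -> dict[int, object]:
    """Resolve item columns named item_<k> or bare integers."""
    cols: dict[int, object] = {}
    for i in range(1, n_items + 1):
        if f"item_{i}" in items.columns:
            cols[i] = f"item_{i}"
        elif i in items.columns:
            cols[i] = i
        else:
            raise KeyError(f"item column for item {i} not found (expected 'item_{i}')")
    return cols


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (n-1) variance estimators.

    Parameters
    ----------
    item_matrix : array-like, shape (n_participants, n_items)

    Returns
    -------
    float, or NaN (with a warning) when the total-score variance is zero.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("item_matrix must be 2-dimensional (participants x items)")
    n, k = X.shape
    if k < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    if n < 3:
        raise ValueError("Cronbach's alpha requires at least 3 participants")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("zero total-score variance; Cronbach's alpha undefined")
        return float("nan")
    item_vars = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_vars / total_var)
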