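"""Discriminating nest sites among revisited locations.

Candidates from the revisitation scan are filtered to nests either with
explicit minimum thresholds on the three revisitation metrics (from prior
knowledge of the species) or with thresholds learned from labeled data by
a classification tree (CART) pruned to the subtree with minimum
cross-validated relative error. Temporally overlapping nest candidates of
one individual are resolved by keeping the most visited (a bird cannot
breed in two places at once); temporally disjoint candidates are kept as
possible sequential attempts. Detection performance is scored as positive
predictive value, sensitivity, false negative rate (on known nests) and
false positive rate (on non-breeder tracks).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, export_text

from .geo_tracks import Track, haversine_m
from .revisitation import BufferSpec, CandidateSite, RevisitationMetrics, find_revisited_locations

__all__ = [
    "FilterSpec",
    "LabeledSite",
    "PerformanceReport",
    "CartResult",
    "filter_candidates",
    "apply_rules",
    "resolve_overlaps",
    "label_sites",
    "fit_cart",
    "evaluate_performance",
    "buffer_sensitivity",
]

FEATURES = ("consec_days", "perc_days_vis", "perc_top_vis")


@dataclass(frozen=True)
class FilterSpec:
    """Minimum thresholds on the three revisitation metrics; 0 disables one."""

    min_consec_days: float = 0.0
    min_days_vis_pct: float = 0.0
    min_top_vis_pct: float = 0.0

    def __post_init__(self) -> None:
        if min(self.min_consec_days, self.min_days_vis_pct, self.min_top_vis_pct) < 0:
            raise ValueError("thresholds must be >= 0")

    def passes(self, m: RevisitationMetrics) -> bool:
        return (
            m.consec_days >= self.min_consec_days
            and m.perc_days_vis >= self.min_days_vis_pct
            and m.perc_top_vis >= self.min_top_vis_pct
        )


@dataclass(frozen=True)
class LabeledSite:
    metrics: RevisitationMetrics
    label: str  # "nest" | "non-nest"
    site: CandidateSite | None = None

    def __post_init__(self) -> None:
        if self.label not in ("nest", "non-nest"):
            raise ValueError(f"label must be 'nest' or 'non-nest', got {self.label!r}")


@dataclass(frozen=True)
class PerformanceReport:
    ppv: float  # % of found sites that match a known nest (NaN if none found)
    sensitivity: float  # % of known nests found (NaN if none known)
    fnr: float  # 100 - sensitivity
    fpr: float  # % of non-breeder tracks with >=1 detection (NaN if none)
    counts: dict


def filter_candidates(candidates: Sequence[CandidateSite], spec: FilterSpec) -> list[CandidateSite]:
    """Candidates meeting every enabled minimum threshold."""
    return [c for c in candidates if spec.passes(c.metrics)]


def apply_rules(candidates: Sequence[CandidateSite], rules: Sequence[FilterSpec]) -> list[CandidateSite]:
    """Disjunction of threshold conjunctions: keep candidates passing any rule."""
    return [c for c in candidates if any(r.passes(c.metrics) for r in rules)]


def _overlaps(a: CandidateSite, b: CandidateSite) -> bool:
    return a.first_day <= b.last_day and b.first_day <= a.last_day


def resolve_overlaps(nests: Sequence[CandidateSite]) -> list[CandidateSite]:
    """Greedy most-visited-first selection of temporally disjoint nests.

    Candidates are taken in order of descending ``n_fixes_in`` (ties:
    earlier first day, then lexicographic center); one is accepted iff its
    visit span does not overlap any already-accepted span.
    """
    order = sorted(
        nests,
        key=lambda c: (-c.n_fixes_in, c.first_day, c.center_lon, c.center_lat, c.center_index),
    )
    accepted: list[CandidateSite] = []
    for cand in order:
        if not any(_overlaps(cand, a) for a in accepted):
            accepted.append(cand)
    for a, b in itertools.combinations(accepted, 2):
        assert not _overlaps(a, b), "resolve_overlaps produced overlapping spans"
    return accepted


def label_sites(
    candidates: Sequence[CandidateSite],
    known_nest_coords: Sequence[tuple[float, float]],
    match_radius: float,
) -> list[LabeledSite]:
    """Label candidates against on-ground nest coordinates.

    A candidate within ``match_radius`` of a known nest is a nest; a
    spatially distinct candidate whose visit span overlaps a matched
    nest's span by at least one day is a non-nest (the bird was breeding
    elsewhere at the time); all others are dropped as undetermined.
    """
    if not known_nest_coords:
        raise ValueError("at least one known nest coordinate is required")
    known = np.asarray(known_nest_coords, dtype=float)
    labeled: list[LabeledSite] = []
    nests: list[CandidateSite] = []
    unmatched: list[CandidateSite] = []
    for c in candidates:
        d = haversine_m(known[:, 0], known[:, 1], c.center_lon, c.center_lat)
        if float(np.min(d)) <= match_radius:
            nests.append(c)
            labeled.append(LabeledSite(c.metrics, "nest", c))
        else:
            unmatched.append(c)
    if not nests:
        warnings.warn("no candidate matched any known nest; nest class is empty")
        return []
    for c in unmatched:
        if any(_overlaps(c, n) for n in nests):
            labeled.append(LabeledSite(c.metrics, "non-nest", c))
    return labeled


# ---------------------------------------------------------------------------
# CART threshold learning

@dataclass
class CartResult:
    rules: list[FilterSpec]  # disjunction of lower-bound conjunctions
    tree: DecisionTreeClassifier
    ccp_alpha: float
    cv_table: pd.DataFrame  # alpha -> cross-validated relative error
    node_counts: pd.DataFrame  # per node: class counts and split
    text: str  # human-readable tree report


def _tree_nest_rules(tree: DecisionTreeClassifier) -> list[dict]:
    """Paths to leaves predicted 'nest', as per-feature bound dicts."""
    t = tree.tree_
    nest_class = int(np.flatnonzero(tree.classes_ == 1)[0])
    rules: list[dict] = []

    def walk(node: int, lower: dict, upper: dict) -> None:
        if t.children_left[node] == -1:  # leaf
            if int(np.argmax(t.value[node][0])) == nest_class:
                rules.append({"lower": dict(lower), "upper": dict(upper)})
            return
        f, thr = FEATURES[t.feature[node]], float(t.threshold[node])
        up = dict(upper)
        up[f] = min(up.get(f, np.inf), thr)
        walk(t.children_left[node], lower, up)  # X[f] <= thr
        lo = dict(lower)
        lo[f] = max(lo.get(f, -np.inf), thr)
        walk(t.children_right[node], lo, upper)  # X[f] > thr
    walk(0, {}, {})
    return rules


def fit_cart(
    data: Sequence[LabeledSite],
    cv_folds: int = 10,
    seed: int = 0,
    min_consec_floor: float | None = None,
    prune: bool = True,
) -> CartResult:
    """Learn threshold rules separating nests from non-nests with CART.

    The tree is grown fully and cost-complexity-pruned to the subtree with
    minimum cross-validated relative error (CV misclassification error
    relative to the root's). Leaf paths predicting "nest" become
    :class:`FilterSpec` rules from their lower bounds (nests are the
    high-metric class; any upper bounds stay visible in the tree report).

    If no rule constrains ``consec_days``, a ``min_consec_floor`` must be
    supplied: attempts failing within the first handful of days carry no
    power, so a floor on consecutive days visited is enforced rather than
    silently accepting 0.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 labeled sites")
    X = np.array([[s.metrics.consec_days, s.metrics.perc_days_vis, s.metrics.perc_top_vis] for s in data])
    y = np.array([1 if s.label == "nest" else 0 for s in data])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    full = DecisionTreeClassifier(random_state=seed).fit(X, y)
    alphas = np.unique(np.clip(full.cost_complexity_pruning_path(X, y).ccp_alphas, 0.0, None))
    root_err = float(np.mean(y != (np.mean(y) >= 0.5)))
    if prune and len(alphas) > 1 and root_err > 0:
        n_splits = min(cv_folds, int(np.min(np.bincount(y))))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(cv.split(X, y))
        rel_err = []
        for a in alphas:
            errs = []
            for tr_idx, te_idx in folds:
                clf = DecisionTreeClassifier(random_state=seed, ccp_alpha=a).fit(X[tr_idx], y[tr_idx])
                errs.append(np.mean(clf.predict(X[te_idx]) != y[te_idx]))
            rel_err.append(float(np.mean(errs)) / root_err)
        rel_err = np.asarray(rel_err)
        # minimum relative error; ties resolved toward the smaller subtree
        best_alpha = float(alphas[np.flatnonzero(rel_err == rel_err.min())[-1]])
        cv_table = pd.DataFrame({"ccp_alpha": alphas, "cv_rel_error": rel_err})
    else:
        best_alpha = 0.0
        cv_table = pd.DataFrame({"ccp_alpha": [0.0], "cv_rel_error": [np.nan]})
    tree = DecisionTreeClassifier(random_state=seed, ccp_alpha=best_alpha).fit(X, y)

    raw_rules = _tree_nest_rules(tree)
    if not raw_rules:
        raise ValueError("pruned tree classifies nothing as a nest; check the labeled data")
    rules = [
        FilterSpec(
            min_consec_days=max(r["lower"].get("consec_days", 0.0), 0.0),
            min_days_vis_pct=max(r["lower"].get("perc_days_vis", 0.0), 0.0),
            min_top_vis_pct=max(r["lower"].get("perc_top_vis", 0.0), 0.0),
        )
        for r in raw_rules
    ]
    if all(r.min_consec_days == 0 for r in rules):
        if min_consec_floor is None:
            raise ValueError(
                "CART produced no threshold on consec_days; supply min_consec_floor "
                "(a biologically reasonable minimum number of consecutive days visited)"
            )
        rules = [replace(r, min_consec_days=float(min_consec_floor)) for r in rules]

    t = tree.tree_
    node_counts = pd.DataFrame(
        {
            "node": np.arange(t.node_count),
            "n_non_nest": [
                int(round(t.value[i, 0, 0] * t.weighted_n_node_samples[i])) for i in range(t.node_count)
            ],
            "n_nest": [int(round(t.value[i, 0, 1] * t.weighted_n_node_samples[i])) for i in range(t.node_count)],
            "feature": [FEATURES[f] if f >= 0 else "leaf" for f in t.feature],
            "threshold": [t.threshold[i] if t.feature[i] >= 0 else np.nan for i in range(t.node_count)],
            "predicted": [("nest" if np.argmax(t.value[i][0]) == 1 else "non-nest") for i in range(t.node_count)],
        }
    )
    text = export_text(tree, feature_names=list(FEATURES), show_weights=True)
    return CartResult(rules=rules, tree=tree, ccp_alpha=best_alpha, cv_table=cv_table, node_counts=node_counts, text=text)


# ---------------------------------------------------------------------------
# performance

def evaluate_performance(
    found_nests: Sequence[CandidateSite],
    known_nest_coords: Sequence[tuple[float, float]],
    nonbreeder_results: Mapping[str, Sequence[CandidateSite]] | None = None,
    match_radius: float = 40.0,
) -> PerformanceReport:
    """Score found nests against known coordinates and non-breeder controls.

    Rates with a zero denominator are reported as NaN, never as 0.
    """
    found = list(found_nests)
    known = np.asarray(known_nest_coords, dtype=float) if len(known_nest_coords) else np.empty((0, 2))
    n_found = len(found)
    found_matched = 0
    for c in found:
        if len(known) and float(np.min(haversine_m(known[:, 0], known[:, 1], c.center_lon, c.center_lat))) <= match_radius:
            found_matched += 1
    known_matched = 0
    for lon, lat in known:
        d = [float(haversine_m(lon, lat, c.center_lon, c.center_lat)) for c in found]
        if d and min(d) <= match_radius:
            known_matched += 1

    ppv = 100.0 * found_matched / n_found if n_found else float("nan")
    sens = 100.0 * known_matched / len(known) if len(known) else float("nan")
    fnr = 100.0 - sens if len(known) else float("nan")
    if nonbreeder_results is not None and len(nonbreeder_results):
        n_nb = len(nonbreeder_results)
        n_fa = sum(1 for v in nonbreeder_results.values() if len(v) > 0)
        fpr = 100.0 * n_fa / n_nb
    else:
        n_nb, n_fa, fpr = 0, 0, float("nan")
    return PerformanceReport(
        ppv=ppv,
        sensitivity=sens,
        fnr=fnr,
        fpr=fpr,
        counts={
            "found": n_found,
            "known": int(len(known)),
            "known_found": known_matched,
            "found_matched": found_matched,
            "nonbreeder_tracks": n_nb,
            "nonbreeder_false_alarms": n_fa,
        },
    )


def detect_nests(
    track: Track,
    buffer: BufferSpec,
    rules: Sequence[FilterSpec],
    tz: str = "UTC",
    skip_missing_days: bool = False,
) -> list[CandidateSite]:
    """Full per-track part-I pipeline: scan, filter by rules, resolve overlaps."""
    cands = find_revisited_locations(track, buffer, tz=tz, skip_missing_days=skip_missing_days)
    return resolve_overlaps(apply_rules(cands, rules))


def buffer_sensitivity(
    tracks: Sequence[Track],
    known_nests: Mapping[str, tuple[float, float]],
    radii: Sequence[float],
    spec: FilterSpec | Sequence[FilterSpec] | None = None,
    cart_config: Mapping | None = None,
    match_radius: float | None = None,
    criterion: str = "sensitivity",
    tz: str = "UTC",
    skip_missing_days: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Re-run the detection pipeline over a grid of buffer radii.

    ``known_nests`` maps track id to the true nest coordinate; tracks
    absent from it are treated as non-breeder controls. Rules are either
    given (``spec``) or learned per radius with CART (``cart_config``
    passed through to :func:`fit_cart`). Returns the radius->performance
    table and the best radius under ``criterion`` (ties broken by PPV).
    """
    radii = list(radii)
    if len(radii) < 2:
        raise ValueError("buffer sensitivity needs at least 2 radii")
    if spec is None and cart_config is None:
        raise ValueError("supply either explicit rules (spec) or a cart_config")
    rows = []
    for r in radii:
        buf = BufferSpec(radius_r=r)
        mr = match_radius if match_radius is not None else r
        cands = {tr.id: find_revisited_locations(tr, buf, tz=tz, skip_missing_days=skip_missing_days) for tr in tracks}
        if spec is not None:
            rules = [spec] if isinstance(spec, FilterSpec) else list(spec)
        else:
            labeled: list[LabeledSite] = []
            for tid, coord in known_nests.items():
                labeled.extend(label_sites(cands.get(tid, []), [coord], mr))
            res = fit_cart(labeled, **dict(cart_config))
            rules = res.rules
        found: list[CandidateSite] = []
        nb: dict[str, list[CandidateSite]] = {}
        for tr in tracks:
            nests = resolve_overlaps(apply_rules(cands[tr.id], rules))
            if tr.id in known_nests:
                found.extend(nests)
            else:
                nb[tr.id] = nests
        rep = evaluate_performance(found, list(known_nests.values()), nb, match_radius=mr)
        rows.append({"radius": r, "ppv": rep.ppv, "sensitivity": rep.sensitivity, "fnr": rep.fnr, "fpr": rep.fpr, **rep.counts})
    table = pd.DataFrame(rows).set_index("radius")
    ranked = table.sort_values([criterion, "ppv"], ascending=False, kind="stable")
    return table, float(ranked.index[0])
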