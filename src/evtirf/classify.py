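"""Colocalization of per-channel detections into single-EV records and
tabulation of the 15 phenotype populations.

An EV that binds k of the four stain antibodies appears as (up to) k spots at
the same position, one per channel. Detections from different channels within
the colocalization radius are merged into one record by greedy agglomeration:
cross-channel detection pairs are visited in order of increasing distance and
two clusters merge when their channel sets are disjoint and every cross-pair
of members lies within the radius. The resulting record's phenotype is the
bitmask of its member channels; a zero bitmask never occurs (every record has
at least one member).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import N_CHANNELS, MarkerPanel
from .detect import concat_nonempty, estimate_background


@dataclass(frozen=True)
class Phenotype:
    """One of the 2^4 - 1 = 15 nonzero marker combinations."""

    bitmask: int
    label: str

    def __post_init__(self) -> None:
        if not 1 <= self.bitmask:
            raise ValueError("counted EVs must have a nonzero bitmask")


def enumerate_populations(panel: MarkerPanel) -> list[Phenotype]:
    """All nonzero phenotype classes of a panel, in canonical order.

    Canonical order: marker count (popcount) descending, then bitmask value
    descending — the quadruple-positive class first, single-positives last.
    A k-marker panel yields 2**k - 1 classes (15 for the 4-marker panels).
    """
    k = len(panel.stain_markers)
    masks = sorted(range(1, 2**k), key=lambda m: (-bin(m).count("1"), -m))
    return [Phenotype(m, panel.label(m)) for m in masks]


EV_COLUMNS = ["image_id", "x_um", "y_um", "bitmask", "label"] + [
    f"intensity_ch{i}" for i in range(N_CHANNELS)
]


class _Clusters:
    """Union-find over detections with per-cluster channel sets."""

    def __init__(self, channels: np.ndarray):
        self.parent = list(range(len(channels)))
        self.members: list[list[int]] = [[i] for i in range(len(channels))]
        self.chansets: list[set[int]] = [{int(c)} for c in channels]

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra].extend(self.members[rb])
        self.chansets[ra] |= self.chansets[rb]


def greedy_partition(
    xy: np.ndarray, channels: np.ndarray, radius_um: float
) -> list[list[int]]:
    """Partition detection indices into EV groups by greedy nearest-pair linkage.

    Cross-channel pairs within ``radius_um`` are visited in order of increasing
    distance (ties by index); two clusters merge when their channel sets are
    disjoint and every cross-pair of members lies within the radius (complete
    linkage). Every detection ends in exactly one group; groups are returned
    in order of their smallest member index, members sorted.
    """
    xy = np.asarray(xy, dtype=float)
    channels = np.asarray(channels, dtype=int)
    clusters = _Clusters(channels)
    pairs = cKDTree(xy).query_pairs(radius_um, output_type="ndarray")
    if len(pairs):
        cross = channels[pairs[:, 0]] != channels[pairs[:, 1]]
        pairs = pairs[cross]
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0], d))
        for k in order:
            i, j = int(pairs[k, 0]), int(pairs[k, 1])
            ri, rj = clusters.find(i), clusters.find(j)
            if ri == rj:
                continue
            if clusters.chansets[ri] & clusters.chansets[rj]:
                continue
            mi, mj = clusters.members[ri], clusters.members[rj]
            dists = np.linalg.norm(xy[mi][:, None, :] - xy[mj][None, :, :], axis=2)
            if np.all(dists <= radius_um):
                clusters.union(ri, rj)
    groups = []
    seen: set[int] = set()
    for i in range(len(channels)):
        r = clusters.find(i)
        if r not in seen:
            seen.add(r)
            groups.append(sorted(clusters.members[r]))
    return groups


def colocalize(
    detections: pd.DataFrame,
    radius_um: float,
    panel: MarkerPanel | None = None,
    channel_shifts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Merge one image's per-channel detections into single-EV records.

    Greedy nearest-pair agglomeration (see module docstring): every detection
    is assigned to exactly one record; members of a record come from distinct
    channels and are pairwise within ``radius_um``. Record position is the
    intensity-weighted mean of member positions; per-channel peak intensities
    are recorded (NaN for channels with no member).

    ``channel_shifts`` is an optional (4, 2) array of per-channel (dx, dy)
    chromatic-offset corrections in um, applied to detection coordinates
    before matching; default identity (channels assumed pre-aligned).
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    panel = panel or MarkerPanel()
    if detections.empty:
        return pd.DataFrame(columns=EV_COLUMNS)
    if detections["image_id"].nunique() > 1:
        raise ValueError("colocalize operates on detections of a single image")

    det = detections.reset_index(drop=True)
    if channel_shifts is not None:
        shifts = np.asarray(channel_shifts, dtype=float)
        det = det.copy()
        det["x_um"] = det["x_um"] + shifts[det["channel"].to_numpy(), 0]
        det["y_um"] = det["y_um"] + shifts[det["channel"].to_numpy(), 1]
    xy = det[["x_um", "y_um"]].to_numpy(dtype=float)
    channels = det["channel"].to_numpy(dtype=int)
    peaks = det["peak_intensity"].to_numpy(dtype=float)

    groups = greedy_partition(xy, channels, radius_um)

    image_id = det["image_id"].iloc[0]
    rows = []
    for mem in groups:
        w = peaks[mem]
        pos = (xy[mem] * w[:, None]).sum(0) / w.sum()
        bitmask = 0
        intens = [float("nan")] * N_CHANNELS
        for m in mem:
            c = int(channels[m])
            bitmask |= 1 << c
            intens[c] = float(peaks[m])
        rows.append(
            dict(
                image_id=image_id,
                x_um=float(pos[0]),
                y_um=float(pos[1]),
                bitmask=bitmask,
                label=panel.label(bitmask),
                **{f"intensity_ch{i}": intens[i] for i in range(N_CHANNELS)},
            )
        )
    records = pd.DataFrame(rows, columns=EV_COLUMNS)
    return records.sort_values(["y_um", "x_um"]).reset_index(drop=True)


def colocalize_all(
    detections: pd.DataFrame,
    radius_um: float,
    panel: MarkerPanel | None = None,
    channel_shifts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply :func:`colocalize` image by image."""
    if detections.empty:
        return pd.DataFrame(columns=EV_COLUMNS)
    parts = [
        colocalize(g, radius_um, panel, channel_shifts)
        for _, g in detections.groupby("image_id", sort=True)
    ]
    return concat_nonempty(parts, EV_COLUMNS)


def count_evs(records: pd.DataFrame, metadata: pd.DataFrame,
              panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Per-image EV totals and per-population counts.

    One row per metadata image (images with zero records get all-zero rows —
    essential for zero-signal frequency analysis), columns: the metadata
    condition fields, ``total``, and one count per phenotype class (canonical
    order). The total equals the sum of the 15 class counts on every row.
    """
    panel = panel or MarkerPanel()
    pops = enumerate_populations(panel)
    meta = metadata.set_index("image_id")
    if len(records):
        unknown = set(records["image_id"]) - set(meta.index)
        if unknown:
            raise ValueError(f"records reference unknown image_ids: {sorted(unknown)[:5]}")
    counts = pd.DataFrame(
        0, index=meta.index, columns=[p.label for p in pops], dtype=int
    )
    if len(records):
        tab = records.groupby(["image_id", "bitmask"]).size()
        for (iid, mask), n in tab.items():
            label = panel.label(int(mask))
            counts.loc[iid, label] = int(n)
    out = meta.copy()
    out["total"] = counts.sum(axis=1)
    out = pd.concat([out, counts], axis=1)
    return out.reset_index()


def composition_fractions(
    count_table: pd.DataFrame,
    panel: MarkerPanel | None = None,
    cluster_markers: tuple[str, str] = ("CD63", "ANXA5"),
) -> dict:
    """Two-cluster composition: fraction of EVs positive for the first cluster
    marker vs (else) positive for the second; others excluded.

    The first marker takes precedence so the clusters are disjoint and the two
    fractions sum to 1 over the included EVs. Returns a dict with the two
    fractions, the included-EV count, and a ``defined`` flag (False when no EV
    carries either marker).
    """
    panel = panel or MarkerPanel()
    b1, b2 = (panel.bit_of(m) for m in cluster_markers)
    n1 = n2 = 0
    for p in enumerate_populations(panel):
        if p.label not in count_table.columns:
            continue
        n = int(count_table[p.label].sum())
        if p.bitmask & b1:
            n1 += n
        elif p.bitmask & b2:
            n2 += n
    total = n1 + n2
    if total == 0:
        return {cluster_markers[0]: float("nan"), cluster_markers[1]: float("nan"),
                "n_included": 0, "defined": False}
    return {cluster_markers[0]: n1 / total, cluster_markers[1]: n2 / total,
            "n_included": total, "defined": True}


def fold_change(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 0.5,
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Per-population ratio of mean per-image counts, a over b.

    ratio = (mean_a + pseudocount) / (mean_b + pseudocount); the Haldane-
    Anscombe pseudocount (default 0.5) guards empty classes. Raw means are
    reported alongside.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    panel = panel or MarkerPanel()
    labels = [p.label for p in enumerate_populations(panel)]
    for lbl in labels:
        if lbl not in counts_a.columns or lbl not in counts_b.columns:
            raise ValueError(f"count tables lack the shared class column {lbl!r}")
    mean_a = counts_a[labels].mean()
    mean_b = counts_b[labels].mean()
    return pd.DataFrame(
        {
            "label": labels,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "ratio": ((mean_a + pseudocount) / (mean_b + pseudocount)).to_numpy(),
        }
    )


def intensity_table(
    records: pd.DataFrame,
    images: dict[str, np.ndarray],
    pixel_size_um: float,
) -> pd.DataFrame:
    """Complete per-EV 4-channel intensity table for correlation analysis.

    Channels in which an EV was detected contribute the background-subtracted
    peak intensity; undetected channels contribute the background-subtracted
    raw value measured at the EV's consensus position, so every row is a
    complete 4-vector.
    """
    rows = []
    bg_cache: dict[tuple[str, int], float] = {}
    for iid, grp in records.groupby("image_id", sort=True):
        stack = images[iid]
        n = stack.shape[1]
        for _, rec in grp.iterrows():
            r = min(max(int(round(rec.y_um / pixel_size_um)), 0), n - 1)
            c = min(max(int(round(rec.x_um / pixel_size_um)), 0), n - 1)
            vals = {}
            for ch in range(N_CHANNELS):
                if (iid, ch) not in bg_cache:
                    bg_cache[(iid, ch)] = estimate_background(stack[ch])[0]
                bg = bg_cache[(iid, ch)]
                peak = rec[f"intensity_ch{ch}"]
                raw = float(stack[ch][r, c])
                vals[f"intensity_ch{ch}"] = (
                    peak - bg if np.isfinite(peak) else raw - bg
                )
            rows.append(dict(image_id=iid, **vals))
    return pd.DataFrame(
        rows, columns=["image_id"] + [f"intensity_ch{i}" for i in range(N_CHANNELS)]
    )


def brute_force_partition(
    xy: np.ndarray, channels: np.ndarray, radius_um: float
) -> list[list[frozenset]]:
    """Exhaustively enumerate optimal valid partitions (test oracle).

    A partition is valid when every group has at most one detection per
    channel and all within-group pairwise distances are <= radius. Optimality
    is lexicographic: fewest groups (maximal colocalization) first, then
    minimal summed within-group pairwise distance. Returns ALL optimal
    partitions (lists of frozensets of detection indices). Small inputs only.
    """
    n = len(channels)
    dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    best_key = [(np.inf, np.inf)]
    best: list[list[frozenset]] = []

    def rec(i: int, groups: list[list[int]], cost: float) -> None:
        # group count and cost are both nondecreasing down a branch
        if len(groups) > best_key[0][0] or (
            len(groups) == best_key[0][0] and cost > best_key[0][1] + 1e-12
        ):
            return
        if i == n:
            key = (len(groups), cost)
            if key[0] < best_key[0][0] or (
                key[0] == best_key[0][0] and cost < best_key[0][1] - 1e-12
            ):
                best_key[0] = key
                best.clear()
                best.append([frozenset(g) for g in groups])
            elif key[0] == best_key[0][0] and abs(cost - best_key[0][1]) <= 1e-12:
                best.append([frozenset(g) for g in groups])
            return
        for g in groups:
            if any(channels[m] == channels[i] for m in g):
                continue
            if any(dist[m, i] > radius_um for m in g):
                continue
            add = sum(dist[m, i] for m in g)
            g.append(i)
            rec(i + 1, groups, cost + add)
            g.pop()
        groups.append([i])
        rec(i + 1, groups, cost)
        groups.pop()

    rec(0, [], 0.0)
    return best
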