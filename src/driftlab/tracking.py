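"""Cross-session neuron identity matching from pre-aligned pixel masks.

Registration of the imaging planes is upstream and out of scope: masks
are assumed to live in a common, session-aligned pixel frame.  Two
masks are candidate matches when their pixel overlap exceeds a
threshold (default 0.75); overlap is intersection-over-union by
default, the stricter symmetric reading of "percentage of overlapping
pixels" (intersection over the smaller mask is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchResult", "overlap", "match_neurons"]

PixelMask = "set[tuple[int, int]]"


@dataclass(frozen=True)
class MatchResult:
    """Accepted cross-session matches: a partial injection between the
    two sessions' neuron id sets."""

    pairs: tuple[tuple[int, int], ...]
    overlaps: tuple[float, ...]

    def as_dict(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def overlap(mask_a, mask_b, method: str = "iou") -> float:
    """Pixel overlap between two masks.

    ``"iou"``: |A & B| / |A | B|; ``"min"``: |A & B| / min(|A|, |B|).
    """
    a, b = set(map(tuple, mask_a)), set(map(tuple, mask_b))
    if not a or not b:
        raise ValueError("masks must be non-empty")
    inter = len(a & b)
    if method == "iou":
        return inter / len(a | b)
    if method == "min":
        return inter / min(len(a), len(b))
    raise ValueError(f"unknown overlap method {method!r}")


def match_neurons(masks_a: dict, masks_b: dict, *,
                  threshold: float = 0.75, method: str = "iou"
                  ) -> MatchResult:
    """Greedy one-to-one matching of neuron masks across two sessions.

    All mask pairs with overlap strictly greater than ``threshold`` are
    candidates; matches are accepted in order of descending overlap
    (ties: lower id in A, then in B), and each neuron is matched at
    most once.
    """
    sets_a = {i: set(map(tuple, m)) for i, m in masks_a.items()}
    sets_b = {i: set(map(tuple, m)) for i, m in masks_b.items()}
    for name, masks in (("A", sets_a), ("B", sets_b)):
        for i, m in masks.items():
            if not m:
                raise ValueError(f"empty mask for neuron {i} in session {name}")

    # candidate pairs via a pixel -> ids index (masks are small and sparse)
    pixel_to_b: dict[tuple[int, int], list] = {}
    for j, m in sets_b.items():
        for px in m:
            pixel_to_b.setdefault(px, []).append(j)
    candidates = []
    for i, ma in sets_a.items():
        touched = set()
        for px in ma:
            touched.update(pixel_to_b.get(px, ()))
        for j in touched:
            ov = overlap(ma, sets_b[j], method)
            if ov > threshold:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_a, used_b = set(), set()
    pairs, overlaps = [], []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        overlaps.append(ov)
    return MatchResult(pairs=tuple(pairs), overlaps=tuple(overlaps))


def load_masks_csv(path) -> dict:
    """Read masks from a CSV pixel list with columns (neuron_id, row, col)."""
    import pandas as pd

    df = pd.read_csv(path)
    return {int(nid): set(zip(g["row"].astype(int), g["col"].astype(int)))
            for nid, g in df.groupby("neuron_id")}


def save_matches_csv(result: MatchResult, path) -> None:
    """Write accepted matches as CSV columns (id_A, id_B, overlap)."""
    import pandas as pd

    pd.DataFrame({
        "id_A": [a for a, _ in result.pairs],
        "id_B": [b for _, b in result.pairs],
        "overlap": list(result.overlaps),
    }).to_csv(path, index=False)
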