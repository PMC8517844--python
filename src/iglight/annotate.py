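"""Substitution-only V/J annotation against a prepared germline reference.

Each read is scanned for the offset at which a reference V allele matches
with the fewest mismatches; every allele achieving that global minimum
distance is retained in ``v_call`` (ties preserved as multi-calls), the
minimum itself becomes ``v_mutation_count``, and ``v_region_start`` is the
smallest offset achieving it.  The J segment is then located the same way in
the remaining 3' tail.  Mismatch counting ignores N positions (read or
reference) and positions inside consensus-extended reference spans.

Indels are not modelled: the inference targets are single-nucleotide
variants, and the simulator plants only substitutions.  This is a documented
limitation for real reads.

For speed, candidate offsets are first proposed by exact matches of each
allele's terminal k-mers (k=20) within the read; whenever no anchor matches,
or the best anchored distance exceeds a small bound, the scan falls back to
the exhaustive all-offsets search, so results equal the brute-force scan.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .model import GermlineAllele, Rearrangement, encode

log = logging.getLogger(__name__)

_ANCHOR_LEN = 20
_FALLBACK_DIST = 6


class _SegmentIndex:
    """Alleles of one segment grouped by length, with anchors for fast offset search."""

    def __init__(self, alleles: list[GermlineAllele]):
        self.by_len: dict[int, dict] = {}
        groups: dict[int, list[GermlineAllele]] = defaultdict(list)
        for a in alleles:
            groups[len(a.sequence)].append(a)
        for L, members in groups.items():
            members = sorted(members, key=lambda a: a.name)
            self.by_len[L] = {
                "names": [a.name for a in members],
                "mat": np.stack([a.codes() for a in members]),
                "valid": np.stack([a.valid_mask() for a in members]),
                "prefixes": {a.sequence[:_ANCHOR_LEN] for a in members},
                "suffixes": {a.sequence[-_ANCHOR_LEN:] for a in members},
            }

    def allele_len(self, name: str) -> int:
        for L, grp in self.by_len.items():
            if name in grp["names"]:
                return L
        raise KeyError(name)


def _distances_at(codes: np.ndarray, grp: dict, offsets: list[int]) -> np.ndarray:
    """(n_offsets, n_alleles) mismatch counts of the read window vs each allele."""
    L = grp["mat"].shape[1]
    windows = np.stack([codes[o: o + L] for o in offsets])  # (n_off, L)
    diff = (
        (windows[:, None, :] != grp["mat"][None, :, :])
        & grp["valid"][None, :, :]
        & (windows[:, None, :] != 0)
    )
    return diff.sum(axis=2)


def _find_all(hay: str, needle: str) -> list[int]:
    hits, start = [], hay.find(needle)
    while start != -1:
        hits.append(start)
        start = hay.find(needle, start + 1)
    return hits


def _group_best(region: str, codes: np.ndarray, L: int, grp: dict):
    """(dmin, min offset at dmin, names achieving dmin at any offset) for one length group."""
    cand = set()
    for p in grp["prefixes"]:
        cand.update(h for h in _find_all(region, p) if h + L <= len(region))
    for s in grp["suffixes"]:
        cand.update(
            h - (L - _ANCHOR_LEN)
            for h in _find_all(region, s)
            if h - (L - _ANCHOR_LEN) >= 0 and h + _ANCHOR_LEN <= len(region)
        )
    offsets = sorted(cand)
    exhaustive = list(range(len(region) - L + 1))
    anchored = bool(offsets)
    if not anchored:
        offsets = exhaustive
    d = _distances_at(codes, grp, offsets)
    dmin = int(d.min())
    if anchored and dmin > _FALLBACK_DIST and len(offsets) < len(exhaustive):
        offsets = exhaustive
        d = _distances_at(codes, grp, offsets)
        dmin = int(d.min())
    where = np.argwhere(d == dmin)
    off = int(offsets[int(where[:, 0].min())])
    names = sorted({grp["names"][j] for j in where[:, 1]})
    return dmin, off, names


def _best_call(
    seq: str, codes: np.ndarray, index: _SegmentIndex, lo: int
) -> tuple[list[str], int, int] | None:
    """Globally best (calls, distance, v-region start) within ``seq[lo:]``.

    ``calls`` lists every allele achieving the global minimum distance (at
    any offset); the reported start is the smallest offset achieving it.
    Returns None when the region is shorter than every allele.
    """
    region = seq[lo:]
    results = [
        _group_best(region, codes[lo:], L, grp)
        for L, grp in sorted(index.by_len.items())
        if len(region) >= L
    ]
    if not results:
        return None
    dstar = min(r[0] for r in results)
    hits = [r for r in results if r[0] == dstar]
    names = sorted({n for r in hits for n in r[2]})
    off = min(r[1] for r in hits)
    return names, dstar, off + lo


def assign_calls(
    reads: list[Rearrangement], reference: list[GermlineAllele]
) -> list[Rearrangement]:
    """Annotate reads with V/J calls, V mismatch count and V-REGION start.

    Reads shorter than every reference V allele are returned unannotated
    (empty ``v_call``) and are excluded by downstream stages.  The result is
    deterministic and invariant to the ordering of the reference list.
    """
    v_index = _SegmentIndex([a for a in reference if a.segment == "V"])
    j_index = _SegmentIndex([a for a in reference if a.segment == "J"])
    if not v_index.by_len:
        raise ValueError("reference contains no V alleles")

    out = []
    n_skipped = 0
    for r in reads:
        codes = encode(r.sequence)
        v = _best_call(r.sequence, codes, v_index, 0)
        if v is None:
            n_skipped += 1
            out.append(
                r.replace(v_call=[], j_call=[], v_mutation_count=None, v_region_start=None)
            )
            continue
        v_names, v_dist, v_start = v
        v_len = v_index.allele_len(v_names[0])
        j_call: list[str] = []
        if j_index.by_len:
            j = _best_call(r.sequence, codes, j_index, v_start + v_len)
            if j is not None:
                j_call = j[0]
        out.append(
            r.replace(
                v_call=v_names,
                j_call=j_call,
                v_mutation_count=v_dist,
                v_region_start=v_start,
            )
        )
    if n_skipped:
        log.warning(
            "%d reads shorter than the shortest reference V; left unannotated", n_skipped
        )
    return out


def brute_force_calls(
    read: Rearrangement, reference: list[GermlineAllele]
) -> tuple[list[str], int, int] | None:
    """Exhaustive all-offsets, all-alleles V scan (independent oracle, small inputs)."""
    codes = encode(read.sequence)
    per_allele = []  # (dist, best offset, name)
    for a in sorted((x for x in reference if x.segment == "V"), key=lambda x: x.name):
        ac, av = a.codes(), a.valid_mask()
        L = len(ac)
        best = None
        for o in range(len(read.sequence) - L + 1):
            w = codes[o: o + L]
            d = int(((w != ac) & av & (w != 0)).sum())
            if best is None or (d, o) < best:
                best = (d, o)
        if best is not None:
            per_allele.append((best[0], best[1], a.name))
    if not per_allele:
        return None
    dstar = min(d for d, _, _ in per_allele)
    hits = [(o, n) for d, o, n in per_allele if d == dstar]
    return sorted(n for _, n in hits), dstar, min(o for o, _ in hits)
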