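"""Independent brute-force oracles used by the tests.

These deliberately share no code with the library: the mapper oracle is a
character-by-character scan of every placement, the GC oracle a single
string concatenation, the Venn oracle a per-element membership enumeration.
"""

from __future__ import annotations


def exhaustive_best_hit(insert: str, catalog, max_mismatch: int = 2):
    """Scan every offset of every record; return (ncrna_id, offset,
    mismatches) for the first placement in (record order, offset) achieving
    the minimal mismatch count <= max_mismatch, else None.  Any position
    involving an N counts as a mismatch."""
    best = None
    best_mm = max_mismatch + 1
    length = len(insert)
    for rec in catalog:
        seq = rec.sequence
        for off in range(len(seq) - length + 1):
            mm = 0
            ok = True
            for a, b in zip(insert, seq[off : off + length]):
                if a != b or a == "N":
                    mm += 1
                    if mm >= best_mm:
                        ok = False
                        break
            if ok and mm < best_mm:
                best = (rec.id, off, mm)
                best_mm = mm
                if mm == 0:
                    return best
    return best


def pooled_gc(sequences) -> float:
    """GC fraction of the concatenation of all sequences."""
    blob = "".join(sequences)
    if not blob:
        return float("nan")
    return (blob.count("G") + blob.count("C")) / len(blob)


def venn_regions(gene_sets: list[set]) -> dict[str, int]:
    """Exclusive membership-pattern counts by per-element enumeration."""
    universe = set().union(*gene_sets)
    out: dict[str, int] = {}
    for element in universe:
        key = "".join("1" if element in s else "0" for s in gene_sets)
        out[key] = out.get(key, 0) + 1
    return out
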