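"""Brute-force AS-event oracle operating on per-base exonic sets.

Independent cross-check for the pairwise event decomposition: instead
of interval arithmetic on exon chains, every transcript is expanded to
the set of its exonic base positions; boundaries, sync points, variant
runs and the canonical event templates are all recomputed from those
sets. Only usable on toy-sized genes.
"""

from __future__ import annotations


def _bases(exons):
    out = set()
    for s, e in exons:
        out.update(range(s, e))
    return out


def _runs(positions):
    """Maximal half-open intervals covering a sorted set of positions."""
    runs = []
    for p in sorted(positions):
        if runs and p == runs[-1][1]:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])
    return [(s, e) for s, e in runs]


def _boundaries(bases):
    """(acceptor-like starts, donor-like ends) derived from the base set."""
    starts = {p for p in bases if p - 1 not in bases}
    ends = {p + 1 for p in bases if p + 1 not in bases}
    return starts, ends


def _gaps(bases):
    """Internal gaps (introns) of a base set as half-open intervals."""
    runs = _runs(bases)
    return [(a[1], b[0]) for a, b in zip(runs, runs[1:])]


def oracle_pair_events(exons_a, exons_b, strand):
    """All typed variant regions between two exon chains.

    Returns a set of (type, anchor_left, anchor_right, region_start,
    region_end) tuples using the same anchor convention as the package
    implementation but computed from per-base sets.
    """
    base_a, base_b = _bases(exons_a), _bases(exons_b)
    events = set()

    # intron retention by direct base containment (flank bases included)
    for bx, by in ((base_a, base_b), (base_b, base_a)):
        for d, a in _gaps(bx):
            if all(p in by for p in range(d - 1, a + 1)):
                events.add(("IR", d, a, d, a))

    if len(_runs(base_a)) < 2 or len(_runs(base_b)) < 2:
        return events  # mono-exon forms participate only in IR

    starts_a, ends_a = _boundaries(base_a)
    starts_b, ends_b = _boundaries(base_b)
    sync = sorted((starts_a & starts_b) | (ends_a & ends_b))

    for c1, c2 in zip(sync, sync[1:]):
        window = set(range(c1, c2))
        in_a, in_b = base_a & window, base_b & window
        if in_a == in_b:
            continue
        if in_a == window or in_b == window:
            continue  # retained-intron pattern, already emitted above
        runs_a, runs_b = _runs(in_a), _runs(in_b)
        ev = _type_from_runs(runs_a, runs_b, c1, c2, strand)
        events.add(ev)
    return events


def _type_from_runs(runs_a, runs_b, c1, c2, strand):
    def strictly_inside(runs):
        return all(c1 < s and e < c2 for s, e in runs)

    if not runs_a or not runs_b:
        frags = runs_a or runs_b
        if strictly_inside(frags):
            return ("ES", c1, c2, frags[0][0], frags[-1][1])
        return ("complex", c1, c2, c1, c2)

    if len(runs_a) == 1 and len(runs_b) == 1:
        (sa, ea), (sb, eb) = runs_a[0], runs_b[0]
        if sa == sb == c1 and ea != eb:
            etype = "A5SS" if strand == "+" else "A3SS"
            return (etype, c1, c2, min(ea, eb), max(ea, eb))
        if ea == eb == c2 and sa != sb:
            etype = "A3SS" if strand == "+" else "A5SS"
            return (etype, c1, c2, min(sa, sb), max(sa, sb))
        if strictly_inside(runs_a) and strictly_inside(runs_b) and (
            ea <= sb or eb <= sa
        ):
            return ("MEE", c1, c2, min(sa, sb), max(ea, eb))
    return ("complex", c1, c2, c1, c2)
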