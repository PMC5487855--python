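"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive each rule from its definition with naive
enumeration, sharing no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

from exofam.io_formats.models import Affection, Genotype, Sex

CARRIER = {Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT}


# ---------------------------------------------------------------------------
# sequence scanning


def scan_adjacent_repeat(
    context: str,
    locus_start: int,
    locus_end: int,
    min_run: int = 6,
    min_copies: int = 3,
    max_unit: int = 6,
    tol: int = 1,
) -> bool:
    """Exhaustive scan: any homopolymer run >= min_run or tandem repeat
    (non-mono unit 2..max_unit, >= min_copies copies) within tol bases of
    [locus_start, locus_end)."""
    n = len(context)
    hits = []
    # every maximal run
    for s in range(n):
        for e in range(s + min_run, n + 1):
            if len(set(context[s:e])) == 1:
                hits.append((s, e))
    # every tandem repeat occurrence
    for u in range(2, max_unit + 1):
        for s in range(n):
            unit = context[s : s + u]
            if len(unit) < u or len(set(unit)) < 2:
                continue
            copies = 1
            while context[s + copies * u : s + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                hits.append((s, s + copies * u))
    for s, e in hits:
        gap = max(s - locus_end, locus_start - e, 0)
        if gap <= tol:
            return True
    return False


# ---------------------------------------------------------------------------
# segregation predicates (naive per-sample loops)


def de_novo_ok(variant, pedigree) -> bool:
    proband = pedigree.proband()
    gts = variant.genotypes
    g = gts.get(proband.sample_id, Genotype.MISSING)
    if g is Genotype.MISSING or g not in CARRIER:
        return False
    others = set()
    if proband.father_id:
        others.add(proband.father_id)
    if proband.mother_id:
        others.add(proband.mother_id)
    for s in pedigree:
        if (
            s.sample_id != proband.sample_id
            and not s.is_founder
            and s.father_id == proband.father_id
            and s.mother_id == proband.mother_id
        ):
            others.add(s.sample_id)
    for sid in others:
        og = gts.get(sid, Genotype.MISSING)
        if og is Genotype.MISSING or og in CARRIER:
            return False
    return True


def ar_hom_ok(variant, pedigree) -> bool:
    gts = variant.genotypes
    obligate = set()
    for s in pedigree:
        if s.affected is Affection.AFFECTED:
            for pid in (s.father_id, s.mother_id):
                if pid and pedigree[pid].affected is not Affection.AFFECTED:
                    obligate.add(pid)
    for s in pedigree:
        g = gts.get(s.sample_id, Genotype.MISSING)
        if g is Genotype.MISSING:
            return False
        if s.affected is Affection.AFFECTED:
            if g is not Genotype.HOM_ALT:
                return False
        elif s.sample_id in obligate:
            if g is not Genotype.HET:
                return False
        elif g is Genotype.HOM_ALT:
            return False
    return True


def xlr_ok(variant, pedigree) -> bool:
    from exofam.io_formats.models import normalize_chrom

    if normalize_chrom(variant.chrom) != "X":
        return False
    gts = variant.genotypes
    carrier_mothers = {
        s.mother_id
        for s in pedigree
        if s.affected is Affection.AFFECTED
        and s.sex is Sex.MALE
        and s.mother_id
    }
    for s in pedigree:
        affected = s.affected is Affection.AFFECTED
        if s.sex is Sex.FEMALE and affected:
            continue  # mild female expression never vetoes (default policy)
        g = gts.get(s.sample_id, Genotype.MISSING)
        if g is Genotype.MISSING:
            return False
        if s.sex is Sex.MALE:
            if affected and g is not Genotype.HEMI_ALT:
                return False
            if not affected and g is Genotype.HEMI_ALT:
                return False
        else:
            if s.sample_id in carrier_mothers and g not in (
                Genotype.HET,
                Genotype.HOM_ALT,
            ):
                return False
            if g is Genotype.HOM_ALT:
                return False
    return True


# ---------------------------------------------------------------------------
# vote / enrichment


def vote_score(calls) -> float:
    score = 0.0
    for c in calls:
        name = getattr(c, "value", c)
        if name == "deleterious":
            score += 1.0
        elif name == "ambiguous":
            score += 0.5
    return score


def hypergeom_upper_tail(overlap, background, marked, draws) -> float:
    """P(X >= overlap) by direct summation of the hypergeometric pmf."""
    total = 0.0
    denom = math.comb(background, draws)
    for k in range(overlap, min(marked, draws) + 1):
        total += math.comb(marked, k) * math.comb(background - marked, draws - k)
    return total / denom


def hypergeom_by_enumeration(query, gene_set, background) -> float:
    """P(overlap >= observed) by enumerating every possible draw of
    |query| genes from the background (feasible only for tiny backgrounds)."""
    background = sorted(background)
    gene_set = set(gene_set) & set(background)
    observed = len(set(query) & gene_set)
    hits = 0
    total = 0
    for draw in itertools.combinations(background, len(set(query))):
        total += 1
        if len(set(draw) & gene_set) >= observed:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# induced module


def induced_intermediates(edges, seeds, max_len) -> set:
    """Greatest fixed point by naive DFS path enumeration."""
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seeds = set(seeds)

    def seed_paths(allowed):
        found = set()
        present = sorted(s for s in seeds if s in adj)

        def dfs(target, node, path):
            if node == target:
                internal = path[1:-1]
                if all(x not in seeds and x in allowed for x in internal):
                    found.update(internal)
                return
            if len(path) - 1 >= max_len:
                return
            for nxt in sorted(adj.get(node, ())):
                if nxt not in path:
                    dfs(target, nxt, path + [nxt])

        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                dfs(b, a, [a])
        return found

    admitted = {n for n in adj if n not in seeds}
    while True:
        nxt = seed_paths(admitted)
        if nxt == admitted:
            return admitted
        admitted = nxt
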