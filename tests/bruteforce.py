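"""Independent brute-force oracles for the association statistics.

These operate on primitive tables (dicts of sets) with explicit nested
loops, deliberately sharing no code with :mod:`pipermine.scoring`.
"""

from __future__ import annotations

CATEGORIES = ("Anxiety/Mood", "Movement/Seizure", "Pain", "Sleep")


def formula_compounds(formula_species, species_compounds):
    """Any-member-species attribution, one explicit loop at a time."""
    out = {}
    for fid in formula_species:
        acc = set()
        for sp in formula_species[fid]:
            for ck in species_compounds.get(sp, ()):
                acc.add(ck)
        out[fid] = acc
    return out


def association_profile(formula_species, species_compounds, formula_cats, ck):
    fc = formula_compounds(formula_species, species_compounds)
    containing = [fid for fid in formula_species if ck in fc[fid]]
    n = len(containing)
    pct = {}
    for cat in CATEGORIES:
        hits = 0
        for fid in containing:
            if cat in formula_cats[fid]:
                hits += 1
        pct[cat] = 100.0 * hits / n if n else 0.0
    return n, pct


def compound_index(formula_species, species_compounds, formula_cats, ck):
    fc = formula_compounds(formula_species, species_compounds)
    per_cat = {}
    for cat in CATEGORIES:
        treating = [fid for fid in formula_species if cat in formula_cats[fid]]
        if not treating:
            per_cat[cat] = None
            continue
        hits = 0
        for fid in treating:
            if ck in fc[fid]:
                hits += 1
        per_cat[cat] = 100.0 * hits / len(treating)
    defined = [v for v in per_cat.values() if v is not None]
    index = sum(defined) / len(defined) if defined else float("nan")
    return index, per_cat


def linkages(formula_species, formula_cats, genus_of, genus_filter=None):
    counts = {}
    for fid in formula_species:
        for sp in formula_species[fid]:
            if genus_filter is not None and genus_of[sp] != genus_filter:
                continue
            for cat in formula_cats[fid]:
                counts[(sp, cat)] = counts.get((sp, cat), 0) + 1
    return counts


def source_counts(species_compounds, genus_of, ck):
    n_target = n_other = 0
    for sp in species_compounds:
        if ck in species_compounds[sp]:
            if genus_of[sp] == "Piper":
                n_target += 1
            else:
                n_other += 1
    return n_target, n_other
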