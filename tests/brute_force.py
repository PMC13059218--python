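"""Independent brute-force re-computation of the whole pipeline.

Pure-Python loops and explicit sorting only — no pandas, no numpy, no calls
into the package's vectorized code paths — so that agreement with the
package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations


def brute_median(values):
    vs = sorted(values)
    n = len(vs)
    if n == 0:
        raise ValueError("median of empty sequence")
    mid = n // 2
    if n % 2:
        return float(vs[mid])
    return (vs[mid - 1] + vs[mid]) / 2.0


def brute_align(value, item):
    return value if item.adverse_high else item.scale_min + item.scale_max - value


def brute_pipeline(rows, items, group_of, n_min):
    """Recompute every stage from respondent rows by explicit counting.

    Parameters
    ----------
    rows : list of dicts with occupation_code, gender and one entry per
        item_id (None = missing).
    items : iterable of ItemDefinition-like objects.
    group_of : dict occupation_code -> jem_group_id.
    n_min : minimum cell size before suppression.

    Returns a dict with keys ``cutoffs`` (item -> individual median),
    ``cell_shares`` ((group, gender) -> item -> share or None),
    ``occ_cutoffs`` (item -> median of cell shares),
    ``code_flags`` ((code, gender) -> item -> 1/0/None) and
    ``strain`` ((code, gender) -> dict or None when incomplete).
    """
    items = list(items)

    cutoffs = {}
    for it in items:
        vals = [
            brute_align(r[it.item_id], it)
            for r in rows
            if r[it.item_id] is not None
        ]
        cutoffs[it.item_id] = brute_median(vals)

    counts = {}  # (group, gender) -> item -> [exposed, nonmissing]
    for r in rows:
        group = group_of.get(r["occupation_code"])
        if group is None:
            continue
        cell = counts.setdefault(
            (group, r["gender"]), {it.item_id: [0, 0] for it in items}
        )
        for it in items:
            v = r[it.item_id]
            if v is None:
                continue
            if brute_align(v, it) > cutoffs[it.item_id]:
                cell[it.item_id][0] += 1
            cell[it.item_id][1] += 1

    cell_shares = {}
    for key, cell in counts.items():
        cell_shares[key] = {
            iid: (None if n < n_min else 100.0 * e / n)
            for iid, (e, n) in cell.items()
        }

    occ_cutoffs = {}
    for it in items:
        vals = [s[it.item_id] for s in cell_shares.values() if s[it.item_id] is not None]
        occ_cutoffs[it.item_id] = brute_median(vals)

    genders = sorted({g for (_, g) in cell_shares})
    code_flags = {}
    for code, group in group_of.items():
        for gender in genders:
            shares = cell_shares.get((group, gender))
            flags = {}
            for it in items:
                s = None if shares is None else shares[it.item_id]
                if s is None:
                    flags[it.item_id] = None
                else:
                    flags[it.item_id] = 1 if s > occ_cutoffs[it.item_id] else 0
            code_flags[(code, gender)] = flags

    demand_ids = [it.item_id for it in items if it.dimension == "demand"]
    control_ids = [it.item_id for it in items if it.dimension == "control"]
    indices = {}
    for key, flags in code_flags.items():
        if any(flags[i] is None for i in demand_ids + control_ids):
            indices[key] = None
        else:
            indices[key] = (
                sum(flags[i] for i in demand_ids),
                sum(flags[i] for i in control_ids),
            )
    complete = [v for v in indices.values() if v is not None]
    med_d = brute_median([d for d, _ in complete])
    med_c = brute_median([c for _, c in complete])

    strain = {}
    for key, pair in indices.items():
        if pair is None:
            strain[key] = None
            continue
        d, c = pair
        hd, lc = d > med_d, c > med_c
        quadrant = (
            "high_strain" if hd and lc
            else "active" if hd
            else "passive" if lc
            else "low_strain"
        )
        strain[key] = {
            "demand_index": d,
            "control_index": c,
            "high_demand": hd,
            "low_control": lc,
            "quadrant": quadrant,
            "job_strain": hd and lc,
        }

    return {
        "cutoffs": cutoffs,
        "cell_shares": cell_shares,
        "occ_cutoffs": occ_cutoffs,
        "code_flags": code_flags,
        "strain": strain,
        "median_demand": med_d,
        "median_control": med_c,
    }
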