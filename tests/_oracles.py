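"""Independent brute-force reference implementations used only by the tests.

Everything here is written directly from the defining rules with plain
Python loops, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Detection oracle: enumerate (strain, donor, site-run) from the definitions
# ---------------------------------------------------------------------------

def brute_force_detect(panel, region_map, min_donor_freq=0.5, min_informative=2):
    """All raw tracts as tuples (strain, recipient_arr, donor, start, end,
    n_informative, mean_psi, length_excl_gaps)."""
    out = []
    arrs = sorted(set(panel.arrangement_of[s] for s in panel.strain_ids))
    chars = [[panel.alleles[i, j].decode() for j in range(len(panel.positions))]
             for i in range(len(panel.strain_ids))]
    for donor in arrs:
        d_rows = [i for i, s in enumerate(panel.strain_ids)
                  if panel.arrangement_of[s] == donor]
        for recipient in arrs:
            if recipient == donor:
                continue
            r_rows = [i for i, s in enumerate(panel.strain_ids)
                      if panel.arrangement_of[s] == recipient]
            for r in r_rows:
                states = []
                for j, pos in enumerate(panel.positions):
                    a = chars[r][j]
                    if a in "N-":
                        states.append((".", 0.0))
                        continue
                    d_alleles = [chars[i][j] for i in d_rows
                                 if chars[i][j] not in "N-"]
                    rest = [chars[i][j] for i in r_rows
                            if i != r and chars[i][j] not in "N-"]
                    if not d_alleles or not rest:
                        states.append((".", 0.0))
                        continue
                    fd = d_alleles.count(a) / len(d_alleles)
                    fr = rest.count(a) / len(rest)
                    if fd >= min_donor_freq and fd > fr:
                        states.append(("I", fd * (1.0 - fr)))
                    elif fd == 0.0 and fr > 0.0:
                        states.append(("C", 0.0))
                    else:
                        states.append((".", 0.0))
                # split informative sites into runs broken by contradictions
                # or region boundaries
                runs = []
                current = []
                for j, (kind, psi) in enumerate(states):
                    pos = int(panel.positions[j])
                    reg = _region_of(region_map, pos)
                    if kind == "I":
                        if current and (reg != current[-1][2] or reg is None):
                            runs.append(current)
                            current = []
                        current.append((pos, psi, reg))
                    elif kind == "C":
                        if current:
                            runs.append(current)
                            current = []
                if current:
                    runs.append(current)
                for run in runs:
                    run = [x for x in run if x[2] is not None]
                    if len(run) < min_informative:
                        continue
                    start, end = run[0][0], run[-1][0]
                    gaps = sum(
                        1 for j, p in enumerate(panel.positions)
                        if start <= p <= end and chars[r][j] == "-")
                    out.append((
                        panel.strain_ids[r], recipient, donor, start, end,
                        len(run),
                        round(sum(p for _, p, _ in run) / len(run), 9),
                        end - start + 1 - gaps,
                    ))
    return out


def _region_of(region_map, pos):
    for rid, s, e in region_map.regions:
        if s <= pos <= e:
            return rid
    return None


def brute_force_dedup(raw):
    """Dedup of oracle tuples under the same two rules, O(n^2).

    Returns tuples (strain, recipient_arr, donors_sorted, start, end,
    n_informative, mean_psi).
    """
    by_strain = {}
    for rec in raw:
        by_strain.setdefault(rec[0], []).append(rec)
    stage1 = []
    for strain, group in by_strain.items():
        # overlap clusters by transitive closure
        clusters = []
        for rec in sorted(group, key=lambda r: (r[3], r[4])):
            placed = False
            for cl in clusters:
                if any(rec[3] <= o[4] and o[3] <= rec[4] for o in cl):
                    cl.append(rec)
                    placed = True
                    break
            if not placed:
                clusters.append([rec])
        # merge clusters that became connected
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(a[3] <= b[4] and b[3] <= a[4]
                           for a in clusters[i] for b in clusters[j]):
                        clusters[i] += clusters.pop(j)
                        merged = True
                        break
                if merged:
                    break
        for cl in clusters:
            rep = sorted(cl, key=lambda r: (-r[5], -(r[4] - r[3]), (r[2],)))[0]
            donors = tuple(sorted(set(r[2] for r in cl)))
            stage1.append((rep[0], rep[1], donors, rep[3], rep[4], rep[5],
                           rep[6]))
    best = {}
    for rec in stage1:
        key = (rec[1], rec[3], rec[4])
        if key not in best or rec[0] < best[key][0]:
            best[key] = rec
    return sorted(best.values())


# ---------------------------------------------------------------------------
# Monte-Carlo tract detection model
# ---------------------------------------------------------------------------

def simulate_observed_spans(phi, psi, n, rng, batch=None):
    """Observed spans from first principles: geometric lengths, Bernoulli
    site marks, outermost-marked-site distance, conditioned on >= 2 marks."""
    spans = []
    while len(spans) < n:
        m = batch or max(1000, 2 * (n - len(spans)))
        lengths = rng.geometric(1.0 - phi, size=m)
        starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        total = int(lengths.sum())
        marks = rng.random(total) < psi
        pos = np.arange(total) - np.repeat(starts, lengths)
        first = np.minimum.reduceat(np.where(marks, pos, 10**9), starts)
        last = np.maximum.reduceat(np.where(marks, pos, -1), starts)
        k = np.add.reduceat(marks.astype(np.int64), starts)
        ok = k >= 2
        spans.extend((last[ok] - first[ok] + 1).tolist())
    return np.asarray(spans[:n], dtype=np.int64)


# ---------------------------------------------------------------------------
# Classical-statistics oracles (direct textbook formulas)
# ---------------------------------------------------------------------------

def chi2_gof_direct(obs, expected_props):
    exp = [sum(obs) * p for p in expected_props]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp)), len(obs) - 1


def chi2_contingency_direct(table):
    table = [list(map(float, row)) for row in table]
    n = sum(sum(row) for row in table)
    rows = [sum(row) for row in table]
    cols = [sum(table[i][j] for i in range(len(table)))
            for j in range(len(table[0]))]
    chi2 = 0.0
    for i in range(len(table)):
        for j in range(len(table[0])):
            e = rows[i] * cols[j] / n
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2, (len(table) - 1) * (len(table[0]) - 1)


def anova_direct(values, groups, focal):
    """One-way ANOVA and focal-vs-pooled-rest contrast, textbook sums of squares."""
    labels = sorted(set(groups))
    data = {g: [v for v, lab in zip(values, groups) if lab == g]
            for g in labels}
    n = len(values)
    k = len(labels)
    gm = sum(values) / n
    ssb = sum(len(d) * (sum(d) / len(d) - gm) ** 2 for d in data.values())
    ssw = sum(sum((x - sum(d) / len(d)) ** 2 for x in d)
              for d in data.values())
    f = (ssb / (k - 1)) / (ssw / (n - k))
    mse = ssw / (n - k)
    w = {g: (1.0 if g == focal else -1.0 / (k - 1)) for g in labels}
    est = sum(w[g] * sum(data[g]) / len(data[g]) for g in labels)
    se = math.sqrt(mse * sum(w[g] ** 2 / len(data[g]) for g in labels))
    return f, est, est / se


def tajima_direct(rows):
    """Tajima's D from the 1989 formulas; ``rows`` is a list of equal-length
    strings without gaps."""
    n = len(rows)
    length = len(rows[0])
    s = 0
    pi = 0.0
    for j in range(length):
        col = [r[j] for r in rows]
        alleles = sorted(set(col))
        if len(alleles) >= 2:
            s += 1
            same = sum(col.count(a) * (col.count(a) - 1) for a in alleles)
            pi += 1.0 - same / (n * (n - 1))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    if s == 0:
        return s, pi, 0.0, None
    theta = s / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = (pi - theta) / math.sqrt(e1 * s + e2 * s * (s - 1))
    return s, pi, theta, d
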