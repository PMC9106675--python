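"""Independent reference implementations used to validate the package.

Everything here is deliberately written without the package's internals:
plain Python loops and hand-rolled union-find instead of KD-trees and
image labelling, recursive enumeration instead of dynamic programming.
These oracles are slow and only usable at small problem sizes, which is
the point -- they provide ground truth the fast implementations must match.
"""

from __future__ import annotations

import math

import numpy as np

# van der Waals radii duplicated here on purpose (shared constants would
# hide a transcription error in either copy)
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


def brute_force_descriptors(structure, ligand, config):
    """Recompute (n, e, p) with plain loops; returns (n, e, p) or None (ND).

    Mirrors the documented definition: ligand-anchored lattice over the
    bounding box + margin, clash removal at vdW + probe, exact ray/sphere
    enclosure, 26-neighbour union-find clustering, component nearest the
    ligand centroid, polar contact counting at the contact cutoff.
    """
    atoms = [
        a
        for a in structure.atoms
        if not a.is_hydrogen and not a.is_hetero
    ]
    coords = [a.coords for a in atoms]
    radii = [_VDW.get(a.element.upper(), 1.70) for a in atoms]
    lig = [a.coords for a in ligand.atoms]
    anchor = [sum(c[k] for c in lig) / len(lig) for k in range(3)]

    s = config.grid_spacing
    lo = [
        math.floor((min(c[k] for c in lig) - anchor[k] - config.region_margin) / s)
        for k in range(3)
    ]
    hi = [
        math.ceil((max(c[k] for c in lig) - anchor[k] + config.region_margin) / s)
        for k in range(3)
    ]

    candidates = {}
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                pt = (anchor[0] + i * s, anchor[1] + j * s, anchor[2] + k * s)
                clash = False
                for c, r in zip(coords, radii):
                    d2 = sum((pt[m] - c[m]) ** 2 for m in range(3))
                    if d2 < (r + config.probe_radius) ** 2:
                        clash = True
                        break
                if not clash:
                    candidates[(i, j, k)] = pt

    dirs = [tuple(d) for d in config.directions()]

    def enclosure(pt):
        blocked = 0
        for d in dirs:
            hit = False
            for c, r in zip(coords, radii):
                v = tuple(c[m] - pt[m] for m in range(3))
                t = sum(v[m] * d[m] for m in range(3))
                if t < 0:
                    continue
                b2 = sum(v[m] ** 2 for m in range(3)) - t * t
                disc = r * r - b2
                if disc < 0:
                    continue
                if t - math.sqrt(disc) <= config.ray_length:
                    hit = True
                    break
            if hit:
                blocked += 1
        return blocked / len(dirs)

    encl = {ijk: enclosure(pt) for ijk, pt in candidates.items()}
    site_ijk = [ijk for ijk, e in encl.items() if e >= config.enclosure_threshold]
    if not site_ijk:
        return None

    # union-find over 26-neighbourhood
    parent = {ijk: ijk for ijk in site_ijk}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    site_set = set(site_ijk)
    for (i, j, k) in site_ijk:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    nb = (i + di, j + dj, k + dk)
                    if nb != (i, j, k) and nb in site_set:
                        ra, rb = find((i, j, k)), find(nb)
                        if ra != rb:
                            parent[ra] = rb

    comps = {}
    for ijk in site_ijk:
        comps.setdefault(find(ijk), []).append(ijk)

    def comp_key(members):
        dmin = min(
            math.dist(candidates[ijk], anchor) for ijk in members
        )
        first = min(members)
        return (round(dmin, 9), -len(members), first)

    members = min(comps.values(), key=comp_key)
    if len(members) < config.min_site_points:
        return None
    n = len(members)
    e = sum(encl[ijk] for ijk in members) / n

    site_pts = [candidates[ijk] for ijk in members]
    total = 0
    weight = 0.0
    charged = {
        ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"),
        ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    }
    for a, c in zip(atoms, coords):
        dmin = min(math.dist(c, pt) for pt in site_pts)
        if dmin <= config.contact_cutoff:
            total += 1
            if a.element.upper() in ("N", "O"):
                w = 2.0 if (a.residue_name.upper(), a.name.upper()) in charged else 1.0
                weight += w
    p = config.hydrophilicity_scale * weight / total if total else 0.0
    return n, e, p


def monte_carlo_enclosure(point, structure, config, n_rays=1_000_000, seed=0):
    """Enclosure fraction from uniformly random ray directions."""
    rng = np.random.default_rng(seed)
    atoms = [a for a in structure.atoms if not a.is_hydrogen and not a.is_hetero]
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_VDW.get(a.element.upper(), 1.70) for a in atoms])
    point = np.asarray(point, dtype=float)
    near = np.linalg.norm(coords - point, axis=1) <= config.ray_length + radii.max()
    coords, radii = coords[near], radii[near]
    blocked = 0
    chunk = 100_000
    done = 0
    while done < n_rays:
        m = min(chunk, n_rays - done)
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rel = coords - point  # (k, 3)
        t = rel @ v.T  # (k, m)
        b2 = (rel**2).sum(axis=1)[:, None] - t**2
        disc = radii[:, None] ** 2 - b2
        hit = (disc >= 0) & (t >= 0) & (t - np.sqrt(np.clip(disc, 0, None)) <= config.ray_length)
        blocked += int(hit.any(axis=0).sum())
        done += m
    return blocked / n_rays


def enumerate_global_alignments(seq_a, seq_b, score_fn, gap_open, gap_extend):
    """Best global alignment score by exhaustive enumeration (affine gaps).

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Only usable
    for sequences of length <= ~7.
    """
    best = [-math.inf]

    def rec(i, j, score, last_op):
        if i == len(seq_a) and j == len(seq_b):
            best[0] = max(best[0], score)
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, score + score_fn(seq_a[i], seq_b[j]), "M")
        if i < len(seq_a):  # gap in seq_b
            cost = gap_extend if last_op == "A" else gap_open
            rec(i + 1, j, score - cost, "A")
        if j < len(seq_b):  # gap in seq_a
            cost = gap_extend if last_op == "B" else gap_open
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0.0, None)
    return best[0]
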