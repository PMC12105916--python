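import numpy as np
import pandas as pd
import pytest

from consunit.io_formats import GenotypeMatrix, OccurrenceSet


def make_occurrences(xy, species=None, crs_code="EPSG:28356"):
    """Projected OccurrenceSet from an (n,2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    df = pd.DataFrame({
        "sample_id": [f"s{i:04d}" for i in range(n)],
        "species_id": species if species is not None else ["sp1"] * n,
        "lon": np.full(n, 153.0),
        "lat": np.full(n, -28.0),
        "x": xy[:, 0],
        "y": xy[:, 1],
    })
    return OccurrenceSet(data=df, crs_code=crs_code)


def make_genotypes(values, reproducibility=None, tags=None, species_id="sp1"):
    """GenotypeMatrix from a 2-D list/array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, L = values.shape
    locus_ids = [f"L{j}" for j in range(L)]
    meta = pd.DataFrame({
        "reproducibility": reproducibility if reproducibility is not None else [1.0] * L,
        "tag_id": tags if tags is not None else [f"t{j}" for j in range(L)],
    }, index=pd.Index(locus_ids, name="locus_id"))
    return GenotypeMatrix(values=values,
                          sample_ids=[f"i{i}" for i in range(n)],
                          locus_ids=locus_ids, locus_meta=meta,
                          species_id=species_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# independent DBSCAN oracle: O(n²) density-reachability closure
# ---------------------------------------------------------------------------

def dbscan_oracle(xy, eps, min_pts):
    """Return (core_component per point or -1, eligible cluster sets, noise mask).

    Clusters are connected components of the core-point graph (edges between
    cores within eps).  A non-core point within eps of a core is a border
    point, assignable to any component owning such a core; points with no
    core neighbour are noise.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if core[i] and comp[i] == -1:
            stack = [i]
            comp[i] = cid
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(neigh[j] & core):
                    if comp[k] == -1:
                        comp[k] = cid
                        stack.append(k)
            cid += 1
    eligible = []
    noise = np.zeros(n, dtype=bool)
    for i in range(n):
        if core[i]:
            eligible.append({comp[i]})
        else:
            cands = {comp[k] for k in np.flatnonzero(neigh[i] & core)}
            eligible.append(cands)
            if not cands:
                noise[i] = True
    return comp, eligible, noise


def check_labels_against_oracle(labels, xy, eps, min_pts):
    """Assert a labeling equals the oracle closure up to cluster renaming."""
    from consunit.spatial_units import NOISE

    comp, eligible, noise = dbscan_oracle(xy, eps, min_pts)
    n = len(xy)
    assert len(labels) == n
    mapping = {}
    for i in range(n):
        if noise[i]:
            assert labels[i] == NOISE, f"point {i} should be noise"
            continue
        assert labels[i] != NOISE, f"point {i} wrongly labeled noise"
        if comp[i] >= 0:  # core: component ↔ label must be a bijection
            if comp[i] in mapping:
                assert mapping[comp[i]] == labels[i]
            else:
                assert labels[i] not in mapping.values()
                mapping[comp[i]] = labels[i]
    for i in range(n):
        if not noise[i] and comp[i] == -1:  # border point
            assert any(mapping.get(c) == labels[i] for c in eligible[i]), \
                f"border point {i} assigned outside its reachable clusters"
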