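"""Structural grouping of the compound panel.

Compounds are described by radius-2 Morgan circular fingerprints (ECFP4,
1024 bits by default), compared with the Tanimoto coefficient, and grouped
by agglomerative hierarchical clustering of the Tanimoto *distance*
(1 - similarity) matrix, cut into a fixed number of groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "fingerprint",
    "fingerprint_set",
    "tanimoto_distance_matrix",
    "hierarchical_groups",
    "read_smiles_table",
]

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 2

_LINKAGES = {"average": "average", "complete": "complete", "ward-like": "ward"}


def fingerprint(smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS):
    """ECFP-style Morgan bit vector for one structure.

    Identical molecules give identical vectors regardless of SMILES
    notation (RDKit canonicalises on parsing).  Unparseable input raises.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def fingerprint_set(
    smiles_by_id: dict[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[list[str], list]:
    """Fingerprints for a panel; errors name the offending compound id."""
    ids, fps = [], []
    for cid, smi in smiles_by_id.items():
        try:
            fps.append(fingerprint(smi, radius=radius, n_bits=n_bits))
        except ValueError as exc:
            raise ValueError(f"compound {cid!r}: {exc}") from exc
        ids.append(cid)
    return ids, fps


def tanimoto_distance_matrix(fps: list) -> np.ndarray:
    """Square symmetric matrix of Tanimoto distances 1 - |A&B| / |A|B|.

    Two empty fingerprints are identical (distance 0, with a warning); an
    empty vs a non-empty fingerprint is maximally distant (1).
    """
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    if any(fp.GetNumOnBits() == 0 for fp in fps):
        warnings.warn("empty fingerprint(s) present; distances set by convention")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = fps[i], fps[j]
            if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
                d = 0.0
            elif a.GetNumOnBits() == 0 or b.GetNumOnBits() == 0:
                d = 1.0
            else:
                d = 1.0 - TanimotoSimilarity(a, b)
            dm[i, j] = dm[j, i] = d
    return dm


def hierarchical_groups(
    dm: np.ndarray, k: int = 5, linkage_method: str = "average"
) -> np.ndarray:
    """Cut an agglomerative dendrogram of the distance matrix into k groups.

    Returns integer labels in 1..k.  Labels are only meaningful up to
    permutation; compare partitions, not label values.
    """
    n = dm.shape[0]
    if dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    z = linkage(squareform(dm, checks=False), method=_LINKAGES[linkage_method])
    return fcluster(z, t=k, criterion="maxclust")


def read_smiles_table(path) -> dict[str, str]:
    """Read an ``id<TAB>smiles`` table (no header) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "smiles"], dtype=str)
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate compound ids: {dups}")
    return dict(zip(df["id"], df["smiles"]))
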