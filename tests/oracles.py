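"""Independent brute-force oracles used to verify the library.

Everything here is deliberately implemented from first principles, with no
imports from complexqa internals beyond plain data access, so results can
be compared against the library's (accelerated) code paths.
"""

from __future__ import annotations

import itertools
import numpy as np


# -- superposition: Horn's quaternion method (independent of Kabsch/SVD) ----

def quaternion_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray):
    """Optimal rigid superposition via the Horn (1987) quaternion method.

    Returns (rotation, translation, rmsd) with mov @ R.T + t ~ ref.
    """
    ref = np.asarray(coords_ref, float)
    mov = np.asarray(coords_mov, float)
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    p = ref - cr
    q = mov - cm
    s = q.T @ p  # correlation matrix
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = q @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    translation = cr - rot @ cm
    return rot, translation, rmsd


def rmsd_after(rotation, translation, mov, ref) -> float:
    moved = np.asarray(mov) @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - np.asarray(ref)) ** 2, axis=1))))


# -- brute-force distance enumerations --------------------------------------

def _residue_heavy(res):
    return [a for a in res.atoms if a.is_heavy]


def brute_contacts(chain_a, chain_b, cutoff: float):
    """All residue pairs with any heavy-atom pair within cutoff (O(N²M²))."""
    contacts = set()
    for ra in chain_a.residues:
        for rb in chain_b.residues:
            for atom_a in _residue_heavy(ra):
                for atom_b in _residue_heavy(rb):
                    d = np.linalg.norm(atom_a.coords - atom_b.coords)
                    if d <= cutoff:
                        contacts.add((ra.key, rb.key))
                        break
                else:
                    continue
                break
    return frozenset(contacts)


def brute_interface_residues(chain_a, chain_b, cutoff: float):
    set_a, set_b = set(), set()
    for key_a, key_b in brute_contacts(chain_a, chain_b, cutoff):
        set_a.add(key_a)
        set_b.add(key_b)
    return set_a, set_b


def brute_clashes(chain_a, chain_b, cutoff: float) -> int:
    n = 0
    for ra in chain_a.residues:
        for rb in chain_b.residues:
            for atom_a in _residue_heavy(ra):
                for atom_b in _residue_heavy(rb):
                    if np.linalg.norm(atom_a.coords - atom_b.coords) < cutoff:
                        n += 1
    return n


# -- exhaustive global alignment (tiny sequences) ---------------------------

def best_alignment_score(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal end-gap-free global alignment score by full enumeration.

    Gap runs cost open + extend*(len-1); runs touching either end of the
    alignment are free. Exponential — only for sequences of length <= ~6.
    """

    best = -np.inf
    la, lb = len(seq_a), len(seq_b)

    def score_path(path) -> float:
        # path: list of moves 'D' (pair), 'A' (gap in b), 'B' (gap in a)
        total = 0.0
        i = j = 0
        runs = []  # (move, start, length)
        for move, group in itertools.groupby(path):
            length = len(list(group))
            runs.append((move, length))
        pos = 0
        for idx, (move, length) in enumerate(runs):
            if move == "D":
                for _ in range(length):
                    total += match if seq_a[i] == seq_b[j] else mismatch
                    i += 1
                    j += 1
            else:
                terminal = idx == 0 or idx == len(runs) - 1
                if not terminal:
                    total += gap_open + gap_extend * (length - 1)
                if move == "A":
                    i += length
                else:
                    j += length
            pos += length
        return total

    def gen(i: int, j: int, path: list):
        nonlocal best
        if i == la and j == lb:
            best = max(best, score_path(path))
            return
        if i < la and j < lb:
            gen(i + 1, j + 1, path + ["D"])
        if i < la:
            gen(i + 1, j, path + ["A"])
        if j < lb:
            gen(i, j + 1, path + ["B"])

    gen(0, 0, [])
    return best


def alignment_score(
    aligned_a: str,
    aligned_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Score one explicit (gapped) alignment under the same scheme."""
    total = 0.0
    columns = list(zip(aligned_a, aligned_b))
    # identify runs of gaps
    runs = []
    for is_gap_col, group in itertools.groupby(
        enumerate(columns), key=lambda item: "-" in item[1]
    ):
        members = list(group)
        runs.append((is_gap_col, members))
    for idx, (is_gap_col, members) in enumerate(runs):
        if not is_gap_col:
            for _, (a, b) in members:
                total += match if a == b else mismatch
        else:
            terminal = idx == 0 or idx == len(runs) - 1
            if terminal:
                continue
            # split a mixed run into maximal same-side runs
            for side, sub in itertools.groupby(
                members, key=lambda item: item[1][0] == "-"
            ):
                length = len(list(sub))
                total += gap_open + gap_extend * (length - 1)
    return total


# -- direct formula ---------------------------------------------------------

def dockq_formula(fnat, irmsd, lrmsd, a=1.5, b=8.5):
    return (fnat + 1 / (1 + (irmsd / a) ** 2) + 1 / (1 + (lrmsd / b) ** 2)) / 3
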