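import numpy as np
import pytest

from aggrevar import ProteinRecord, ScoreTrack


@pytest.fixture
def toy_protein():
    # neutral context - hydrophobic core - neutral context
    return ProteinRecord("p1", "SGSNGS" + "IVLVIVL" + "SGKNGS")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(pid: str, scores) -> ScoreTrack:
    return ScoreTrack(pid, np.asarray(scores, dtype=float))


def brute_force_runs(scores, threshold=5.0, min_len=5):
    """Quadratic-time oracle: all maximal runs of score > threshold."""
    scores = list(scores)
    L = len(scores)
    runs = []
    for start in range(L):
        for end in range(start, L):
            if all(s > threshold for s in scores[start : end + 1]):
                left_ok = start == 0 or scores[start - 1] <= threshold
                right_ok = end == L - 1 or scores[end + 1] <= threshold
                if left_ok and right_ok and end - start + 1 >= min_len:
                    runs.append((start + 1, end + 1))
    return sorted(set(runs))


PDB_ATOM = (
    "ATOM  {serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
)


def make_pdb(atoms, chain="A"):
    """Build PDB text from (resseq, resname, atom_name, element, x, y, z)."""
    lines = []
    for i, (resseq, resname, name, element, x, y, z) in enumerate(atoms, 1):
        lines.append(
            PDB_ATOM.format(
                serial=i,
                name=f" {name}" if len(name) < 4 else name,
                resname=resname,
                chain=chain,
                resseq=resseq,
                x=x,
                y=y,
                z=z,
                element=element,
            )
        )
    lines.append("END\n")
    return "".join(lines)
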