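"""Pluggable RNA secondary-structure folding backends.

The default backend is the ViennaRNA thermodynamic nearest-neighbor model
(python bindings, when importable).  A pure-python base-pair-maximization
backend (Nussinov dynamic program) is bundled as a clearly labelled
non-thermodynamic fallback: its "energy" is minus the number of base
pairs, useful only for structure-shape tests, never for thermodynamic
claims.
"""

from __future__ import annotations

from typing import Optional

__all__ = ["fold", "pair_table", "FoldingBackendUnavailable", "available_backends"]

#: folding temperature used throughout, degrees Celsius (the organism's
#: natural growth temperature rather than the 37C thermodynamic default)
DEFAULT_TEMPERATURE = 24.0

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
#: minimal hairpin loop size for the fallback backend
_MIN_LOOP = 3


class FoldingBackendUnavailable(RuntimeError):
    pass


def available_backends() -> list[str]:
    backends = []
    try:
        import RNA  # noqa: F401

        backends.append("viennarna")
    except ImportError:
        pass
    backends.append("nussinov")
    return backends


def fold(
    sequence: str,
    temperature: float = DEFAULT_TEMPERATURE,
    backend: str = "auto",
) -> tuple[str, float]:
    """Minimum-free-energy structure (dot-bracket) and energy of a sequence.

    ``backend='auto'`` prefers the thermodynamic engine (ViennaRNA) and
    raises with configuration instructions when only explicitly asked-for
    backends are missing.  Energy is kcal/mol for the thermodynamic
    backend, and minus the base-pair count for the ``'nussinov'``
    fallback (non-thermodynamic; test use only).  Folding is
    deterministic.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        return "", 0.0
    if any(b not in "ACGUN" for b in seq):
        raise ValueError(f"non-RNA characters in sequence: {sequence[:30]}...")
    if backend == "auto":
        backend = "viennarna" if "viennarna" in available_backends() else "nussinov"
    if backend == "viennarna":
        try:
            import RNA
        except ImportError:
            raise FoldingBackendUnavailable(
                "ViennaRNA python bindings not importable; install the "
                "'viennarna' package or pass backend='nussinov'"
            )
        md = RNA.md()
        md.temperature = float(temperature)
        fc = RNA.fold_compound(seq, md)
        structure, mfe = fc.mfe()
        return structure, float(mfe)
    if backend == "nussinov":
        return _nussinov(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


def _nussinov(seq: str) -> tuple[str, float]:
    """Base-pair maximization (Nussinov). Energy = -(number of pairs)."""
    n = len(seq)
    if n < _MIN_LOOP + 2:
        return "." * n, 0.0
    best = [[0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            val = best[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                if (seq[k], seq[j]) in _WATSON_CRICK:
                    left = best[i][k - 1] if k > i else 0
                    cand = left + best[k + 1][j - 1] + 1
                    if cand > val:
                        val = cand
            best[i][j] = val
    structure = ["."] * n

    def _traceback(i: int, j: int) -> None:
        while i < j:
            if best[i][j] == best[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - _MIN_LOOP):
                if (seq[k], seq[j]) in _WATSON_CRICK:
                    left = best[i][k - 1] if k > i else 0
                    if left + best[k + 1][j - 1] + 1 == best[i][j]:
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            _traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - defensive
                break

    _traceback(0, n - 1)
    return "".join(structure), -float(best[0][n - 1])


def pair_table(structure: str) -> list[Optional[int]]:
    """Map position -> paired partner (0-based) or None, from dot-bracket."""
    stack: list[int] = []
    table: list[Optional[int]] = [None] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return table
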