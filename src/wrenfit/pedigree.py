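"""Recursive pedigree kinship (the tabular method).

Used to compute ground-truth inbreeding coefficients for simulated
populations: the pedigree inbreeding coefficient of an offspring equals the
kinship (coancestry) of its two genetic parents.  Founders are assumed
unrelated and non-inbred.
"""

from __future__ import annotations


class Pedigree:
    """A pedigree with memoised recursive kinship.

    Parents may be ``None`` (founder).  Individuals must be added before
    their offspring so that the recursion can always descend to the
    younger member of a dyad.
    """

    def __init__(self) -> None:
        self._parents: dict[object, tuple[object | None, object | None]] = {}
        self._order: dict[object, int] = {}
        self._cache: dict[tuple, float] = {}

    def add(self, ind, dam=None, sire=None) -> None:
        if ind in self._parents:
            raise ValueError(f"individual {ind!r} already in pedigree")
        for p in (dam, sire):
            if p is not None and p not in self._parents:
                raise ValueError(f"parent {p!r} of {ind!r} not in pedigree")
        self._parents[ind] = (dam, sire)
        self._order[ind] = len(self._order)

    def __contains__(self, ind) -> bool:
        return ind in self._parents

    def parents(self, ind):
        return self._parents[ind]

    def kinship(self, a, b) -> float:
        """Coancestry theta(a, b); relatedness of the dyad is 2*theta."""
        if a not in self._parents or b not in self._parents:
            raise KeyError("both individuals must be in the pedigree")
        return self._kinship(a, b)

    def _kinship(self, a, b) -> float:
        # recurse on the more recently added individual; founders terminate
        if self._order[a] < self._order[b]:
            a, b = b, a
        key = (a, b)
        got = self._cache.get(key)
        if got is not None:
            return got
        dam, sire = self._parents[a]
        if a == b:
            if dam is None or sire is None:
                val = 0.5
            else:
                val = 0.5 * (1.0 + self._kinship(dam, sire))
        elif dam is None and sire is None:
            val = 0.0
        else:
            val = 0.0
            if dam is not None:
                val += 0.5 * self._kinship(dam, b)
            if sire is not None:
                val += 0.5 * self._kinship(sire, b)
        self._cache[key] = val
        return val

    def inbreeding(self, ind) -> float:
        """Pedigree f of *ind*: kinship of its parents (0 for founders)."""
        dam, sire = self._parents[ind]
        if dam is None or sire is None:
            return 0.0
        return self._kinship(dam, sire)

    def relatedness(self, a, b) -> float:
        """Pedigree relatedness r = 2 * kinship."""
        return 2.0 * self.kinship(a, b)
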