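"""Named, ordered parameter vectors shared by the clock and PK-PD models.

Every model parameter lives in a :class:`ParameterSet`: a flat float vector
with a stable name ordering, named lookup, and non-negativity validation.
Fitting routines operate on (subsets of) the flat vector; the ODE builders
consume values by name.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["ParameterSet"]


class ParameterSet:
    """Ordered mapping parameter-name -> non-negative rate/constant.

    Parameters
    ----------
    names : sequence of str
        Unique parameter names; the ordering is preserved and defines the
        layout of :meth:`as_array`.
    values : sequence of float
        One value per name; all must be finite and >= 0 (rates and
        constants in this model family are non-negative by construction).
    """

    def __init__(self, names, values):
        names = list(names)
        values = np.asarray(values, dtype=float).copy()
        if len(names) != values.size:
            raise ValueError("names and values length mismatch")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dup}")
        if not np.all(np.isfinite(values)):
            raise ValueError("parameter values must be finite")
        if np.any(values < 0):
            bad = [n for n, v in zip(names, values) if v < 0]
            raise ValueError(f"negative parameter values for: {bad}")
        self._names = names
        self._index = {n: i for i, n in enumerate(names)}
        self._values = values

    # -- container protocol -------------------------------------------------
    @property
    def names(self) -> list:
        return list(self._names)

    @property
    def n_par(self) -> int:
        return len(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name) -> bool:
        return name in self._index

    def __getitem__(self, key) -> float:
        if isinstance(key, str):
            return float(self._values[self._index[key]])
        return float(self._values[key])

    def index(self, name: str) -> int:
        return self._index[name]

    def as_array(self) -> np.ndarray:
        return self._values.copy()

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self._names, self._values)}

    # -- functional updates -------------------------------------------------
    def replace(self, **updates) -> "ParameterSet":
        """Return a copy with the named entries replaced."""
        vals = self._values.copy()
        for name, v in updates.items():
            if name not in self._index:
                raise KeyError(f"unknown parameter: {name!r}")
            vals[self._index[name]] = v
        return type(self)(self._names, vals)

    def with_array(self, values) -> "ParameterSet":
        """Return a copy with the full value vector replaced (same names)."""
        return type(self)(self._names, values)

    def subset_array(self, names) -> np.ndarray:
        return np.array([self[n] for n in names], dtype=float)

    def updated_from(self, names, values) -> "ParameterSet":
        return self.replace(**dict(zip(names, np.asarray(values, float))))

    def copy(self) -> "ParameterSet":
        return type(self)(self._names, self._values)

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(list(d.keys()), list(d.values()))

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        return (isinstance(other, ParameterSet)
                and self._names == other._names
                and np.array_equal(self._values, other._values))

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n_par={self.n_par})"
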