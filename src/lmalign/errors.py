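"""Exception hierarchy for lmalign.

Distinct classes exist so the CLI can map failure modes to distinct exit
codes and so library users can catch precisely what they expect.
"""


class LmalignError(Exception):
    """Base class for all lmalign errors."""


class ParseError(LmalignError):
    """A coordinate file could not be read or parsed."""


class EmptyInputError(LmalignError):
    """A file yielded zero chains or zero selected atoms."""


class UnlikeMoleculesError(LmalignError):
    """Chains of one assembly differ in selected-point count.

    The algorithms require strictly like molecules: every chain must
    contribute exactly the same number of points.
    """


class DimensionMismatchError(LmalignError):
    """Two assemblies disagree in molecule count N or points-per-molecule n."""


class ChainIDMismatchError(LmalignError):
    """Chain ID sets of the two files do not coincide (simple algorithm)."""


class PermutationGuardError(LmalignError):
    """Brute-force enumeration refused: N! mappings exceed the guard."""

    def __init__(self, n_molecules: int, n_permutations: int, max_n: int):
        self.n_molecules = n_molecules
        self.n_permutations = n_permutations
        self.max_n = max_n
        super().__init__(
            f"reference algorithm refused for N={n_molecules}: "
            f"{n_permutations:,} permutations would be examined "
            f"(guard max_N={max_n}; raise it to force)"
        )


class SingularQuaternionError(LmalignError):
    """A zero-length quaternion cannot define a rotation."""


class UndefinedRateError(LmalignError):
    """Rejection rate undefined: no pair is similar under the reference RMSD."""
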