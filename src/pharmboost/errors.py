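"""Exception hierarchy for pharmboost."""


class PharmboostError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(PharmboostError, ValueError):
    """Input file or record set is structurally unusable (e.g. no protein atoms)."""


class LigandSelectorError(PharmboostError, ValueError):
    """The ligand selector matched no residue group."""


class AmbiguousLigandError(PharmboostError, ValueError):
    """The ligand selector matched more than one residue group."""

    def __init__(self, selector: str, candidates):
        self.candidates = list(candidates)
        names = ", ".join(str(c) for c in self.candidates)
        super().__init__(
            f"ligand selector {selector!r} is ambiguous; candidates: {names}"
        )


class GenerationError(PharmboostError, ValueError):
    """A synthetic geometry request is infeasible (e.g. non-Euclidean distances)."""


class TrainingError(PharmboostError, RuntimeError):
    """Model training cannot proceed (single-class data, first learner too weak...)."""


class DegenerateDataError(PharmboostError, ValueError):
    """Data is valid but degenerate for the requested computation (e.g. no actives)."""
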