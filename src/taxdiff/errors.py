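"""Exception hierarchy for taxdiff."""


class TaxdiffError(Exception):
    """Base class for all taxdiff errors."""


class FormatError(TaxdiffError):
    """Input file could not be parsed in the expected format."""


class CycleError(TaxdiffError):
    """The asserted is-a hierarchy contains a cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"cyclic is-a hierarchy involving concept {member!r}")


class ReferentialIntegrityError(TaxdiffError):
    """A concept refers to a parent that does not exist in the release."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            "unknown parent identifier(s): " + ", ".join(repr(o) for o in self.offenders)
        )


class DuplicateIdError(TaxdiffError):
    """The same concept identifier appears more than once."""


class ParameterError(TaxdiffError):
    """An operation parameter is out of its valid range."""


class InfeasibleTargetError(TaxdiffError):
    """No parameter value can satisfy the requested node budget."""


class NodeLookupError(TaxdiffError):
    """A requested node/root identifier is not present."""


class FeasibilityError(TaxdiffError):
    """A requested synthetic edit cannot be applied to the base release."""
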