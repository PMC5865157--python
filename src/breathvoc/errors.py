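"""Exception hierarchy.

Validation errors (bad user input) derive from :class:`InputError`;
rule-applicability failures derive from :class:`RuleError` so callers can
distinguish "your file is malformed" from "this rule does not apply to this
molecule".
"""


class BreathvocError(Exception):
    """Base class for all package errors."""


class InputError(BreathvocError, ValueError):
    """Malformed or out-of-range user input (files, scores, configs)."""


class FormulaError(InputError):
    """Unparseable or chemically invalid elemental formula."""


class RuleError(BreathvocError):
    """A prediction rule does not apply to the given compound/platform."""


class TransformDomainError(RuleError):
    """An ion transform would yield a non-positive m/z."""


class UnsupportedClassError(RuleError):
    """Chemical class outside the rule table."""


class UnsupportedReagentError(RuleError):
    """CI reagent without a parameterised rule set."""


class UnsupportedChannelError(RuleError):
    """No reaction channel known for this class/precursor pair."""


class ExtrapolationError(InputError):
    """Retention time falls outside the alkane-ladder span."""


class DegenerateFitError(BreathvocError):
    """Regression input with zero variance in the predictor."""


class UndefinedStatisticError(BreathvocError):
    """A statistic (RSD, LOD, concentration, composition) is undefined."""
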