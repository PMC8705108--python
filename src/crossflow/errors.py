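"""Exception hierarchy for cross-flow ultrafiltration runs.

Each failure mode a membrane operator can hit (cake formation by freezing,
axial flow exhaustion, permeate flow reversal, non-convergence of the wall
concentration fixed point, bad configuration) gets its own class so that the
CLI can map them onto distinct exit codes.
"""


class CrossflowError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CrossflowError, ValueError):
    """Argument outside the physical domain of a constitutive correlation."""


class FreezingError(CrossflowError):
    """Wall volume fraction reached the hard-sphere freezing transition.

    Signals (reversible) cake formation by crystallization/jamming; the
    fluid-state constitutive expressions no longer apply.
    """


class FlowExhaustionError(CrossflowError):
    """Axial centerline velocity dropped to zero inside the channel.

    The permeate drain exceeds the axial feed: the operating point is outside
    the model's validity (no through-flow at the outlet).
    """


class PermeateReversalError(CrossflowError):
    """Osmotic pressure locally exceeds the transmembrane pressure.

    The Darcy-Starling flux would point back into the lumen somewhere.
    """


class ConvergenceError(CrossflowError):
    """Wall-concentration fixed point did not reach tolerance."""


class ConfigError(CrossflowError, ValueError):
    """Invalid or inconsistent run configuration."""
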