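"""Exception hierarchy for the gaitfloor package."""


class GaitFloorError(Exception):
    """Base class for all gaitfloor errors."""


class InvalidGeometryError(GaitFloorError):
    """Non-positive module dimensions or otherwise impossible floor geometry."""


class ValidationError(GaitFloorError):
    """A value violates its documented range (e.g. capacitance outside [0, 1])."""


class UnknownModuleError(GaitFloorError):
    """A sensor message references a module id not present in the floor layout."""


class OutOfOrderError(GaitFloorError):
    """A message stream is not sorted by timestamp; streams are never re-sorted silently."""


class EmptyInputError(GaitFloorError):
    """An operation that requires at least one element received none."""


class DegenerateWalkError(GaitFloorError):
    """A walk without usable displacement: no walking direction can be defined."""


class InvalidGridError(GaitFloorError):
    """Non-positive grid spacing or radius."""


class InsufficientDataError(GaitFloorError):
    """Too few walks/participants/windows for the requested split or training run."""


class ConfigError(GaitFloorError):
    """Inconsistent configuration (e.g. regression head with classification loss)."""
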