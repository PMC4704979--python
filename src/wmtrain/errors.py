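"""Exception hierarchy shared by all wmtrain modules."""


class WmTrainError(Exception):
    """Base class for every error raised by wmtrain."""


class ConfigError(WmTrainError, ValueError):
    """An exercise/ladder/program configuration violates its invariants."""


class InputError(WmTrainError, ValueError):
    """A response stream, answer value or data file is malformed."""


class StateError(WmTrainError, RuntimeError):
    """An operation was attempted from an illegal state (e.g. spawning
    from an unassigned record)."""


class IntegrityError(WmTrainError, RuntimeError):
    """Referential-integrity or checksum failure in the datastore."""
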