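"""Exception hierarchy for cellvr.

All user-facing failures derive from :class:`CellVRError` so the CLI can
distinguish user/data errors (exit 1) from environment errors (exit 2).
"""


class CellVRError(Exception):
    """Base class for all cellvr errors."""


class IngestError(CellVRError):
    """A container could not be read or lacks required structure."""


class StructuralError(IngestError):
    """The file opened but its internal layout violates an invariant."""


class SceneError(CellVRError):
    """A scene violates the data-model contract."""


class PackageError(CellVRError):
    """Base for scene-package (zip) errors."""


class MissingMemberError(PackageError):
    """A member promised by the manifest is absent from the archive."""


class PackageParseError(PackageError):
    """A member exists but is not parseable JSON (or wrong shape)."""


class PackageConsistencyError(PackageError):
    """Members parse but contradict the manifest or each other."""


class NoVelocityError(CellVRError):
    """Typed signal: the dataset carries no embedded velocity vectors."""


class RegistryError(CellVRError):
    """Handoff-service registry failure (unknown id, invalid upload)."""
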