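"""Group-based access control.

Each stored object carries exactly one ownership record (owner user plus
owning group); each group has one policy level on the four-step ladder

    private < group_read < group_read_annotate < public_read

Reads are allowed to admins, owners, group members at ``group_read`` or
above, and anyone when the level is ``public_read``.  Annotation requires
admin, ownership, or group membership at exactly ``group_read_annotate``
(public visibility does not imply write access).  These are pure decision
rules; the store enforces them on every read path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AccessError

LEVELS = ("private", "group_read", "group_read_annotate", "public_read")
LEVEL_ORDER = {name: i for i, name in enumerate(LEVELS)}


@dataclass(frozen=True)
class Principal:
    """The acting user: id, group memberships, admin flag."""

    user_id: str
    group_ids: frozenset[str] = field(default_factory=frozenset)
    is_admin: bool = False

    def __post_init__(self):
        if not self.user_id:
            raise AccessError("principal user_id must be non-empty")
        object.__setattr__(self, "group_ids", frozenset(self.group_ids))


#: Default single-user desk principal: an administrator.
ADMIN = Principal("admin", frozenset(), True)


@dataclass(frozen=True)
class Ownership:
    owner: str
    group: str


def check_level(level: str) -> str:
    if level not in LEVEL_ORDER:
        raise AccessError(f"unknown permission level {level!r}; expected one of {LEVELS}")
    return level


def can_read(p: Principal, own: Ownership, level: str) -> bool:
    check_level(level)
    if p.is_admin or p.user_id == own.owner:
        return True
    if level == "public_read":
        return True
    if own.group in p.group_ids:
        return LEVEL_ORDER[level] >= LEVEL_ORDER["group_read"]
    return False


def can_annotate(p: Principal, own: Ownership, level: str) -> bool:
    check_level(level)
    if p.is_admin or p.user_id == own.owner:
        return True
    return own.group in p.group_ids and level == "group_read_annotate"
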