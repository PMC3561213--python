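"""Exception hierarchy shared across the engine."""


class DrugrecError(Exception):
    """Base class for all engine errors."""


class TerminologyError(DrugrecError):
    """Malformed code, unknown code, or an invalid hierarchy."""


class HierarchyCycleError(TerminologyError):
    """The parent relation of a code system contains a cycle."""

    def __init__(self, members):
        self.members = list(members)
        super().__init__(f"cycle in code hierarchy: {' -> '.join(self.members)}")


class DslSyntaxError(DrugrecError):
    """Syntax error in the condition/rule language, with position info."""

    def __init__(self, message, *, line=None, column=None, filename=None):
        self.line = line
        self.column = column
        self.filename = filename
        where = []
        if filename is not None:
            where.append(str(filename))
        if line is not None:
            where.append(f"line {line}")
        if column is not None:
            where.append(f"col {column}")
        prefix = f"{':'.join(where)}: " if where else ""
        super().__init__(prefix + message)


class ConditionCycleError(DrugrecError):
    """Condition definitions reference each other in a cycle."""

    def __init__(self, members):
        self.members = sorted(members)
        super().__init__(f"cyclic condition definitions: {', '.join(self.members)}")


class UndefinedConditionError(DrugrecError):
    """A c/ atom references a condition with no definition."""

    def __init__(self, name, referenced_from=None):
        self.name = name
        self.referenced_from = referenced_from
        msg = f"undefined condition {name!r}"
        if referenced_from:
            msg += f" (referenced from {referenced_from!r})"
        super().__init__(msg)


class KnowledgeBaseError(DrugrecError):
    """Validation failure in an assembled knowledge base."""
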