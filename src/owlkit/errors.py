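"""Exception hierarchy.

Commands map these onto exit codes: check failures (incoherence, verify/report
violations) are status 1, usage/configuration problems are status 2, and I/O or
parse problems are status 3.
"""


class OwlkitError(Exception):
    """Base class for all toolkit errors."""


class UsageError(OwlkitError):
    """Bad command line or bad API arguments."""


class ConfigurationError(UsageError):
    """A required option or configuration value is missing or malformed."""


class PrefixError(OwlkitError):
    """A CURIE uses a prefix not present in the prefix map."""


class RoleConflictError(OwlkitError):
    """One identifier is used in two incompatible entity roles."""

    def __init__(self, entity, roles):
        self.entity = entity
        self.roles = tuple(sorted(roles))
        super().__init__(f"{entity} used in conflicting roles: {', '.join(self.roles)}")


class ParseError(OwlkitError):
    """Syntax error in an input file."""

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}"
        super().__init__(f"{where}: {message}" if where else message)


class UnsupportedConstructError(ParseError):
    """Input uses an OWL construct outside the supported fragment."""

    def __init__(self, construct, path=None, line=None):
        self.construct = construct
        super().__init__(f"unsupported construct: {construct}", path=path, line=line)


class ConversionError(OwlkitError):
    """Axioms cannot be expressed in the requested output format."""

    def __init__(self, message, axioms=()):
        self.axioms = list(axioms)
        super().__init__(message)


class UnresolvedImportError(OwlkitError):
    """An imported ontology IRI has no catalog mapping."""

    def __init__(self, iri):
        self.iri = iri
        super().__init__(f"unresolved import: {iri}")


class UnknownTermError(OwlkitError):
    """A requested term does not occur in the ontology."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__("unknown term(s): " + ", ".join(str(t) for t in self.terms))


class IncoherentOntologyError(OwlkitError):
    """The ontology is inconsistent or has unsatisfiable classes."""

    def __init__(self, unsatisfiable):
        self.unsatisfiable = sorted(unsatisfiable)
        names = ", ".join(str(c) for c in self.unsatisfiable)
        super().__init__(f"ontology is incoherent; unsatisfiable classes: {names}")


class EquivalentPairError(OwlkitError):
    """Distinct named classes were inferred to be equivalent."""

    def __init__(self, pairs):
        self.pairs = sorted(pairs)
        rendered = "; ".join(f"{a} == {b}" for a, b in self.pairs)
        super().__init__(f"inferred equivalent class pairs: {rendered}")


class PatternError(UsageError):
    """A regular expression in a selector or check does not compile."""


class ProfileError(OwlkitError):
    """A report profile is malformed or a custom check query fails to parse."""


class RepairError(OwlkitError):
    """Repair cannot proceed (e.g. a cycle of term replacements)."""


class TemplateError(OwlkitError):
    """A template table is malformed; addressed by row/column when known."""

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column {column}")
        super().__init__((" / ".join(where) + ": " if where else "") + message)


class SparqlParseError(ParseError):
    """Query text does not parse in the supported SPARQL subset."""
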