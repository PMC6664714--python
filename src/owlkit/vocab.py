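"""Well-known IRIs and the default prefix map.

Annotation-property defaults follow OBO community conventions (rdfs:label for
labels, IAO:0000115 for textual definitions, oboInOwl for xrefs and subsets,
IAO:0100001 for term replacements); all of them are overridable where a
consuming operation takes a configuration argument.
"""

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"
DCTERMS = "http://purl.org/dc/terms/"
OBO = "http://purl.obolibrary.org/obo/"
OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"

RDF_TYPE = RDF + "type"
RDF_FIRST = RDF + "first"
RDF_REST = RDF + "rest"
RDF_NIL = RDF + "nil"

RDFS_LABEL = RDFS + "label"
RDFS_COMMENT = RDFS + "comment"
RDFS_SUBCLASSOF = RDFS + "subClassOf"
RDFS_SUBPROPERTYOF = RDFS + "subPropertyOf"
RDFS_IS_DEFINED_BY = RDFS + "isDefinedBy"

OWL_CLASS = OWL + "Class"
OWL_OBJECT_PROPERTY = OWL + "ObjectProperty"
OWL_ANNOTATION_PROPERTY = OWL + "AnnotationProperty"
OWL_NAMED_INDIVIDUAL = OWL + "NamedIndividual"
OWL_ONTOLOGY = OWL + "Ontology"
OWL_THING = OWL + "Thing"
OWL_NOTHING = OWL + "Nothing"
OWL_EQUIVALENT_CLASS = OWL + "equivalentClass"
OWL_DISJOINT_WITH = OWL + "disjointWith"
OWL_ALL_DISJOINT_CLASSES = OWL + "AllDisjointClasses"
OWL_MEMBERS = OWL + "members"
OWL_RESTRICTION = OWL + "Restriction"
OWL_ON_PROPERTY = OWL + "onProperty"
OWL_SOME_VALUES_FROM = OWL + "someValuesFrom"
OWL_INTERSECTION_OF = OWL + "intersectionOf"
OWL_IMPORTS = OWL + "imports"
OWL_VERSION_IRI = OWL + "versionIRI"
OWL_DEPRECATED = OWL + "deprecated"
OWL_AXIOM = OWL + "Axiom"
OWL_ANNOTATED_SOURCE = OWL + "annotatedSource"
OWL_ANNOTATED_PROPERTY = OWL + "annotatedProperty"
OWL_ANNOTATED_TARGET = OWL + "annotatedTarget"

# Constructs recognised but outside the supported fragment; reads fail loudly.
OWL_UNSUPPORTED = {
    OWL + "unionOf": "owl:unionOf",
    OWL + "complementOf": "owl:complementOf",
    OWL + "allValuesFrom": "owl:allValuesFrom",
    OWL + "hasValue": "owl:hasValue",
    OWL + "oneOf": "owl:oneOf",
    OWL + "minCardinality": "owl:minCardinality",
    OWL + "maxCardinality": "owl:maxCardinality",
    OWL + "cardinality": "owl:cardinality",
    OWL + "qualifiedCardinality": "owl:qualifiedCardinality",
    OWL + "hasSelf": "owl:hasSelf",
    OWL + "propertyChainAxiom": "owl:propertyChainAxiom",
    OWL + "inverseOf": "owl:inverseOf",
}

XSD_STRING = XSD + "string"
XSD_BOOLEAN = XSD + "boolean"
XSD_INTEGER = XSD + "integer"
XSD_DECIMAL = XSD + "decimal"
XSD_ANYURI = XSD + "anyURI"

DEFINITION = OBO + "IAO_0000115"
REPLACED_BY = OBO + "IAO_0100001"
XREF = OBOINOWL + "hasDbXref"
IN_SUBSET = OBOINOWL + "inSubset"
LICENSE = DCTERMS + "license"
TITLE = DCTERMS + "title"

DEFAULT_PREFIXES = {
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
    "dcterms": DCTERMS,
    "obo": OBO,
    "oboInOwl": OBOINOWL,
}
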