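"""Default lookup tables shared by the normalizer, the matchers and the
synthetic-corpus generator.

All tables are plain dicts/sets so a config file can replace or extend them;
the matcher and the generator are injected with the *same* tables by default
so that closed-world recovery tests are meaningful. Keys and values are
lower-case, whitespace-normalized strings.
"""

from __future__ import annotations

# British -> American spellings, anatomy-flavoured. The normalizer applies
# these word-by-word; ontology primary labels are assumed American.
ANGLICISMS: dict[str, str] = {
    "oesophagus": "esophagus",
    "oesophageal": "esophageal",
    "caecum": "cecum",
    "caecal": "cecal",
    "coeliac": "celiac",
    "haemolymph": "hemolymph",
    "haematopoietic": "hematopoietic",
    "haemoglobin": "hemoglobin",
    "haemorrhage": "hemorrhage",
    "haemangioma": "hemangioma",
    "anaemia": "anemia",
    "leukaemia": "leukemia",
    "tumour": "tumor",
    "colour": "color",
    "fibre": "fiber",
    "centre": "center",
    "foetus": "fetus",
    "foetal": "fetal",
    "oedema": "edema",
    "oestrogen": "estrogen",
    "oestrous": "estrous",
    "diarrhoea": "diarrhea",
    "gynaecological": "gynecological",
    "paediatric": "pediatric",
    "orthopaedic": "orthopedic",
    "anaesthesia": "anesthesia",
    "ileocaecal": "ileocecal",
    "praeputial": "preputial",
    "sulphur": "sulfur",
    "goitre": "goiter",
    "calibre": "caliber",
    "grey": "gray",
    "vapour": "vapor",
    "behavioural": "behavioral",
    "haemopoietic": "hemopoietic",
    "amnionic": "amniotic",
    "aetiology": "etiology",
    "odour": "odor",
    "humour": "humor",
}

# adjective -> anatomical noun; covers the described adjectival-annotation
# failure mode ("Abdominal" for "Abdomen", "Arterial" for "Artery").
ADJECTIVE_TO_NOUN: dict[str, str] = {
    "abdominal": "abdomen",
    "arterial": "artery",
    "hepatic": "liver",
    "renal": "kidney",
    "cardiac": "heart",
    "gastric": "stomach",
    "pulmonary": "lung",
    "splenic": "spleen",
    "cerebral": "cerebrum",
    "cerebellar": "cerebellum",
    "pancreatic": "pancreas",
    "tracheal": "trachea",
    "esophageal": "esophagus",
    "duodenal": "duodenum",
    "colonic": "colon",
    "rectal": "rectum",
    "vesical": "bladder",
    "uterine": "uterus",
    "ovarian": "ovary",
    "testicular": "testis",
    "dermal": "dermis",
    "cranial": "cranium",
    "femoral": "femur",
    "tibial": "tibia",
    "sternal": "sternum",
    "vertebral": "vertebra",
    "retinal": "retina",
    "corneal": "cornea",
    "lingual": "tongue",
    "laryngeal": "larynx",
    "pharyngeal": "pharynx",
    "aortic": "aorta",
    "venous": "vein",
    "neural": "nerve",
    "muscular": "muscle",
    "osseous": "bone",
    "thymic": "thymus",
    "adrenal": "adrenal gland",
    "mammary": "mammary gland",
}

# shorthand annotation -> list of full ontology labels it denotes; one
# shorthand may legitimately expand to several classes ("both ventricles").
SHORTHAND: dict[str, list[str]] = {
    "antrum": ["pyloric antrum"],
    "both ventricles": ["left ventricle of heart", "right ventricle of heart"],
    "both atria": ["left atrium of heart", "right atrium of heart"],
    "both kidneys": ["left kidney", "right kidney"],
    "ba lavage": ["bronchoalveolar lavage fluid"],
    "acc": ["anterior cingulate cortex"],
    "bm": ["bone marrow"],
}

# words that look plural but are not; never singularized.
PLURAL_EXCEPTIONS: frozenset[str] = frozenset(
    {
        "pancreas",
        "testis",
        "penis",
        "epididymis",
        "pelvis",
        "iris",
        "uterus",
        "esophagus",
        "anus",
        "mucosa",  # guard against -s heuristics on stems
        "fibrosus",
        "thymus",
        "ileus",
        "plexus",
        "sinus",
        "villus",
        "humerus",
        "tarsus",
        "meniscus",
        "annulus",
        "bronchus",
        "fundus",
        "ramus",
        "talus",
        "biceps",
        "series",
        "species",
        "pons",
        "lens",
        "atlas",
        "axis",
        "cortex",
        "vas",
        "glans",
    }
)

# Latin/Greek irregular plural -> singular, applied before the English rules.
IRREGULAR_PLURALS: dict[str, str] = {
    "vertebrae": "vertebra",
    "ganglia": "ganglion",
    "mitochondria": "mitochondrion",
    "bronchi": "bronchus",
    "alveoli": "alveolus",
    "villi": "villus",
    "glomeruli": "glomerulus",
    "nuclei": "nucleus",
    "fungi": "fungus",
    "testes": "testis",
    "pelves": "pelvis",
    "epididymides": "epididymis",
    "cortices": "cortex",
    "matrices": "matrix",
    "appendices": "appendix",
    "teeth": "tooth",
    "feet": "foot",
    "gingivae": "gingiva",
    "aortae": "aorta",
    "retinae": "retina",
    "vasa": "vas",
}

# procedure words that imply a location but are not anatomy; stripped before
# matching ("colon pinch biopsy" -> "colon").
PROCESS_STOP_PHRASES: tuple[str, ...] = (
    "pinch biopsy",
    "lavage",
    "biopsy",
    "flush",
    "aspirate",
    "smear",
    "swab",
    "resection",
    "homogenate",
)

# species lexicon: binomials plus common vernaculars, for species stripping.
SPECIES_LEXICON: tuple[str, ...] = (
    "homo sapiens",
    "mus musculus",
    "rattus norvegicus",
    "bos taurus",
    "pan troglodytes",
    "gallus gallus",
    "danio rerio",
    "xenopus laevis",
    "macaca mulatta",
    "sus scrofa",
    "canis familiaris",
    "oryctolagus cuniculus",
    "human",
    "mouse",
    "murine",
    "rat",
    "bovine",
    "cow",
    "chimpanzee",
    "chicken",
    "zebrafish",
    "frog",
    "macaque",
    "pig",
    "porcine",
    "dog",
    "rabbit",
)

# species mixture matching the study corpus composition (fractions of terms
# carrying each binomial); used by the synthetic generator for realism only.
SPECIES_MIXTURE: dict[str, float] = {
    "Homo sapiens": 0.5088,
    "Mus musculus": 0.2791,
    "Rattus norvegicus": 0.1061,
    "Bos taurus": 0.0169,
    "Pan troglodytes": 0.0163,
    "Gallus gallus": 0.0150,
    "Danio rerio": 0.0117,
    "Xenopus laevis": 0.0104,
    "Macaca mulatta": 0.0085,
    "Sus scrofa": 0.0078,
    "Canis familiaris": 0.0194,
}

# composite separators / connectors
DELIMITERS: tuple[str, ...] = ("/", ";", ",", "+", "&")
CONJUNCTIONS: tuple[str, ...] = (" and ", " with ", " plus ")
LOCATIVE_CONNECTORS: tuple[str, ...] = (
    "flushed from",
    "derived from",
    "dissected from",
    "isolated from",
    "from",
)
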