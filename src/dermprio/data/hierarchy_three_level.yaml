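# Three-level diagnosis hierarchy (coarse -> mid -> fine).
#
# The coarse groupings used for hierarchical training are a clinical
# reading of how dermatologists organise these 13 categories; the exact
# assignment of a few classes (notably SLent and Haem) is genuinely
# ambiguous and this file is the editable, best-effort default rather
# than a verified ground truth.  BCC and ActKer can present either
# pigmented or non-pigmented, so their mid-level label may be overridden
# per sample (pigmented / non-pigmented / uncertain).
levels:
  - name: level1
    categories: [melanocytic, non-melanocytic, uncertain]
    mapping:
      SebKer: non-melanocytic
      ActKer: non-melanocytic
      Nev: melanocytic
      MolCont: non-melanocytic
      Haem: non-melanocytic
      UncNeop: uncertain
      Drmfib: non-melanocytic
      SLent: non-melanocytic
      PenFib: non-melanocytic
      VWart: non-melanocytic
      OtMalNeop: non-melanocytic
      BCC: non-melanocytic
      MM: melanocytic
  - name: level2
    categories: [pigmented-melanocytic, pigmented-non-melanocytic, non-pigmented, uncertain, other]
    mapping:
      SebKer: pigmented-non-melanocytic
      ActKer: non-pigmented
      Nev: pigmented-melanocytic
      MolCont: non-pigmented
      Haem: other
      UncNeop: uncertain
      Drmfib: pigmented-non-melanocytic
      SLent: pigmented-non-melanocytic
      PenFib: non-pigmented
      VWart: non-pigmented
      OtMalNeop: other
      BCC: non-pigmented
      MM: pigmented-melanocytic
    overridable: [BCC, ActKer]
    override_values:
      pigmented: pigmented-non-melanocytic
      non-pigmented: non-pigmented
      uncertain: uncertain
# The fine level is always the 13-way diagnosis itself.
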