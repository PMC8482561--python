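{
 "questions": [
  {"id": 1, "view": "structural",
   "text": "In which chromosome is the variation located?",
   "requires": ["Variation", "Chromosome"]},
  {"id": 2, "view": "structural",
   "text": "What is the position of the variation in the GRCh37 assembly?",
   "requires": ["Variation", "Assembly", "GenomicPosition"]},
  {"id": 3, "view": "structural",
   "text": "What is the position of the variation in the GRCh38 assembly?",
   "requires": ["Variation", "ChromosomeElement"]},
  {"id": 4, "view": "transcription",
   "text": "What gene is affected by the variation?",
   "requires": ["Variation", "Gene"]},
  {"id": 5, "view": "transcription",
   "text": "what are the exons of the affected gene?",
   "requires": ["Gene", "Exon"]},
  {"id": 6, "view": "transcription",
   "text": "what are the introns of the affected gene?",
   "requires": ["Gene", "Intron"]},
  {"id": 7, "view": "transcription",
   "text": "what are the regulatory elements of the affected gene?",
   "requires": ["Gene", "RegulatoryElement"]},
  {"id": 8, "view": "transcription",
   "text": "What proteins are affected by the variation?",
   "requires": ["Variation", "Protein"]},
  {"id": 9, "view": "transcription",
   "text": "What domains compose the affected protein?",
   "requires": ["Protein", "ProteinDomain"]},
  {"id": 10, "view": "transcription",
   "text": "What is the coding sequence of the affected transcript?",
   "requires": ["MessengerRNA", "CodingSequence"]},
  {"id": 11, "view": "transcription",
   "text": "What is the sequence of the untranslated regions of the affected mRNA?",
   "requires": ["MessengerRNA", "FivePrimeUTR", "ThreePrimeUTR"]},
  {"id": 12, "view": "variation",
   "text": "What is the type of the variation?",
   "requires": ["Variation"]},
  {"id": 13, "view": "variation",
   "text": "What are the alleles of the variation?",
   "requires": ["Variation"]},
  {"id": 14, "view": "variation",
   "text": "What is the allele frequency of the variation in the European population?",
   "requires": ["Variation", "Population"]},
  {"id": 15, "view": "variation",
   "text": "What is the allele frequency of the variation in the individual under study?",
   "requires": ["Variation", "Individual"]},
  {"id": 16, "view": "pathway",
   "text": "What pathway is regulated by the affected protein?",
   "requires": ["Protein", "Pathway", "TakesPart"]},
  {"id": 17, "view": "pathway",
   "text": "What specific process of the pathway is affected by the variation?",
   "requires": ["Pathway", "Process"]},
  {"id": 18, "view": "pathway",
   "text": "What are the inputs and outputs of the affected process?",
   "requires": ["Process", "Input", "Output"]},
  {"id": 19, "view": "bibliography",
   "text": "What are the external references of the variation",
   "requires": ["Variation", "DataBankEntry", "ReferenceLink"]},
  {"id": 20, "view": "bibliography",
   "text": "What is the bibliography regarding the affected gene?",
   "requires": ["Gene", "BibliographyEntry", "ReferenceLink"]}
 ]
}
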