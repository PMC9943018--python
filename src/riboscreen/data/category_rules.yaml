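# Default ordered rules assigning antisense-regulated genes to ten
# functional groups. First matching rule wins; structural classes
# (pseudogene, transposase) precede functional ones, and the final
# fallback is "other". Keywords are case-insensitive substrings matched
# against gene annotation labels (product descriptions, COG ids, EC
# numbers); length bounds are in nucleotides.
min_real_gene_nt: 300
rules:
  - category: pseudogene
    kind: pseudogene
  - category: transposase
    keywords: [transposase, insertion sequence, "IS element", transposon]
    cogs: [COG2801, COG2963, COG3039, COG3385, COG3547]
  - category: tf
    keywords: [transcriptional regulator, transcription factor,
               transcriptional repressor, transcriptional activator,
               DNA-binding regulator, antiterminator protein]
  - category: signaling
    keywords: [histidine kinase, signal transduction, response regulator,
               diguanylate cyclase, quorum, chemotaxis, GGDEF, EAL domain,
               autoinducer]
  - category: transporter
    keywords: [transporter, ABC-type transport, ABC transporter, permease,
               symporter, antiporter, efflux, uptake system, exporter]
  - category: cofactor
    keywords: [cobalamin-dependent, B12-dependent, adenosylcobalamin-dependent,
               TPP-dependent, thiamine pyrophosphate-dependent,
               molybdopterin-dependent, molybdenum cofactor-requiring,
               FAD-dependent, SAM-radical, coenzyme-dependent]
  - category: interconversion
    keywords: [aminotransferase, transaminase, amidase, amidohydrolase,
               synthetase, synthase, dehydrogenase, phosphatase,
               acyltransferase, methyltransferase, reductase, hydrolase,
               lyase, isomerase, mutase, epimerase, "EC "]
  - category: hypothetical
    max_length: 299
    requires_ortholog: false
  - category: uncharacterized
    min_length: 300
    requires_ortholog: true
  - category: other
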