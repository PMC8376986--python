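# Hypothesized facial configurations per emotion category, as AU-set
# variants.  Transcribed from the basic-emotion literature's published
# prototype lists (EMFACS-style prototypes plus the self-conscious-emotion
# displays); "with or without" alternatives are expanded into explicit
# variants.  AU identifiers above 27 are head/eye movements that cannot be
# coded from a static photograph and are flagged dynamic.
#
# This file is data, not code: substitute your own prototype registry by
# passing a file with the same schema (category -> list of {aus, dynamic}).
amusement:
  - {aus: [6, 12, 26, 53], dynamic: [53]}
  - {aus: [6, 12, 53], dynamic: [53]}
anger:
  - {aus: [4, 5, 7, 23]}
  - {aus: [4, 5, 7, 10, 23, 25]}
  - {aus: [4, 5, 7, 17, 23, 24]}
  - {aus: [4, 7, 24]}
awe:
  - {aus: [1, 2, 5, 25, 26]}
  - {aus: [1, 2, 5, 25]}
  - {aus: [1, 2, 5, 26]}
contempt:
  - {aus: [14]}
  - {aus: [12, 14]}
disgust:
  - {aus: [9, 15, 16]}
  - {aus: [9, 16, 25]}
  - {aus: [9, 16, 26]}
  - {aus: [10, 16, 25]}
  - {aus: [10, 16, 26]}
embarrassment:
  - {aus: [12, 24, 51, 54, 64], dynamic: [51, 54, 64]}
  - {aus: [51, 54, 64], dynamic: [51, 54, 64]}
fear:
  - {aus: [1, 2, 5]}
  - {aus: [1, 2, 5, 25]}
  - {aus: [1, 2, 5, 26]}
  - {aus: [1, 2, 5, 27]}
  - {aus: [1, 2, 4, 5, 20, 25]}
  - {aus: [1, 2, 4, 5, 20, 26]}
  - {aus: [1, 2, 4, 5, 20, 27]}
happiness:
  - {aus: [6, 12]}
  - {aus: [12, 25]}
  - {aus: [6, 12, 25]}
interest:
  - {aus: [1, 2, 12]}
  - {aus: [1, 2]}
pride:
  - {aus: [53, 64], dynamic: [53, 64]}
sadness:
  - {aus: [1, 4, 15]}
  - {aus: [1, 4, 15, 17]}
  - {aus: [6, 15]}
shame:
  - {aus: [54, 64], dynamic: [54, 64]}
surprise:
  - {aus: [1, 2, 5, 26]}
  - {aus: [1, 2, 5, 27]}
  - {aus: [1, 2, 26]}
  - {aus: [1, 2, 27]}
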