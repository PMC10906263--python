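# Clade -> group tables used to split occurrences into crown and stem
# mammals.  `base` applies to every scenario; each named scenario adds the
# clades whose placement depends on the treatment of haramiyidans.
# Matching is by the most specific lineage entry present in either list, so
# a family entry overrides an order entry, which overrides a class entry.
#
# Edit or replace this file (see `load_scenario(config_path=...)`) to change
# the taxonomy without touching code.
base:
  crown:
    - Mammalia
    - Eutriconodonta
    - Multituberculata
    - Theria
    - Metatheria
    - Eutheria
    - Monotremata
    - Australosphenida
    - Symmetrodonta
    - Trechnotheria
    - Dryolestida
  stem:
    - Osteichthyes        # PBDB files non-mammalian synapsids under this class
    - Synapsida
    - Therapsida
    - Cynodontia
    - Mammaliaformes
    - Morganucodonta
    - Docodonta
    - Tritylodontidae
    - Tritheledontidae
    - Traversodontidae
    - Dicynodontia
    - Anomodontia
    - Gorgonopsia
    - Therocephalia
    - Probainognathia

scenarios:
  haramiyida_crown:
    crown:
      - Haramiyida
      - Haramiyidae
      - Haramiyaviidae
      - Eleutherodontidae
      - Gondwanatheria
      - Sudamericidae
      - Ferugliotheriidae
    stem: []
  haramiyida_stem:
    crown: []
    stem:
      - Haramiyida
      - Haramiyidae
      - Haramiyaviidae
      - Eleutherodontidae
      - Gondwanatheria
      - Sudamericidae
      - Ferugliotheriidae
  haramiyida_polyphyletic:
    crown:
      - Haramiyida
      - Eleutherodontidae
      - Gondwanatheria
      - Sudamericidae
      - Ferugliotheriidae
    stem:
      - Haramiyidae
      - Haramiyaviidae
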