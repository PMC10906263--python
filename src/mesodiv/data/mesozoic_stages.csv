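name,older_ma,younger_ma,series
Induan,251.9,251.2,Lower Triassic
Olenekian,251.2,247.2,Lower Triassic
Anisian,247.2,242.0,Middle Triassic
Ladinian,242.0,237.0,Middle Triassic
Carnian,237.0,227.0,Upper Triassic
Norian,227.0,208.5,Upper Triassic
Rhaetian,208.5,201.4,Upper Triassic
Hettangian,201.4,199.3,Lower Jurassic
Sinemurian,199.3,192.9,Lower Jurassic
Pliensbachian,192.9,184.2,Lower Jurassic
Toarcian,184.2,174.7,Lower Jurassic
Aalenian,174.7,170.9,Middle Jurassic
Bajocian,170.9,168.2,Middle Jurassic
Bathonian,168.2,165.3,Middle Jurassic
Callovian,165.3,161.5,Middle Jurassic
Oxfordian,161.5,154.8,Upper Jurassic
Kimmeridgian,154.8,149.2,Upper Jurassic
Tithonian,149.2,145.0,Upper Jurassic
Berriasian,145.0,139.8,Lower Cretaceous
Valanginian,139.8,132.6,Lower Cretaceous
Hauterivian,132.6,125.8,Lower Cretaceous
Barremian,125.8,121.4,Lower Cretaceous
Aptian,121.4,113.0,Lower Cretaceous
Albian,113.0,100.5,Lower Cretaceous
Cenomanian,100.5,93.9,Upper Cretaceous
Turonian,93.9,89.8,Upper Cretaceous
Coniacian,89.8,86.3,Upper Cretaceous
Santonian,86.3,83.6,Upper Cretaceous
Campanian,83.6,72.1,Upper Cretaceous
Maastrichtian,72.1,66.0,Upper Cretaceous
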