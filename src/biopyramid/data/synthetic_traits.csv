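species,common_name,body_mass_kg,group_size,home_range_km2,trophic_group,order
Vulpes_vulpes,red fox,6.0,1.0,2.0,secondary_consumer,Carnivora
Canis_lupus,wolf,29.9,5.0,150.0,secondary_consumer,Carnivora
Felis_silvestris,European wildcat,4.25,1.0,2.5,secondary_consumer,Carnivora
Martes_martes,pine marten,1.3,1.0,2.2,secondary_consumer,Carnivora
Meles_meles,Eurasian badger,12.0,2.0,1.5,omnivore,Carnivora
Ursus_arctos,brown bear,95.4,1.0,120.0,omnivore,Carnivora
Cervus_elaphus,red deer,71.997,5.0,4.5,primary_consumer,Artiodactyla
Capreolus_capreolus,roe deer,24.4995,2.0,0.6,primary_consumer,Artiodactyla
Sus_scrofa,wild boar,75.002,4.0,5.0,primary_consumer,Artiodactyla
Sciurus_vulgaris,red squirrel,0.297,1.0,0.06,primary_consumer,Rodentia
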