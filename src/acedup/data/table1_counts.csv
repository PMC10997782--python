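population,year,phenotype_class,count
Yopougon,2012,[RR],0
Yopougon,2012,"[SS, D1+]",1
Yopougon,2012,"[SS, D1-]",39
Yopougon,2012,"[RS, D1+]",3
Yopougon,2012,"[RS, D1-]",12
Yopougon,2015,[RR],1
Yopougon,2015,"[SS, D1+]",0
Yopougon,2015,"[SS, D1-]",13
Yopougon,2015,"[RS, D1+]",25
Yopougon,2015,"[RS, D1-]",20
Yopougon,2016,[RR],1
Yopougon,2016,"[SS, D1+]",2
Yopougon,2016,"[SS, D1-]",18
Yopougon,2016,"[RS, D1+]",18
Yopougon,2016,"[RS, D1-]",19
Yamoussoukro,2012,[RR],0
Yamoussoukro,2012,"[SS, D1+]",1
Yamoussoukro,2012,"[SS, D1-]",20
Yamoussoukro,2012,"[RS, D1+]",14
Yamoussoukro,2012,"[RS, D1-]",11
Yamoussoukro,2015,[RR],1
Yamoussoukro,2015,"[SS, D1+]",2
Yamoussoukro,2015,"[SS, D1-]",10
Yamoussoukro,2015,"[RS, D1+]",15
Yamoussoukro,2015,"[RS, D1-]",20
Yamoussoukro,2016,[RR],0
Yamoussoukro,2016,"[SS, D1+]",1
Yamoussoukro,2016,"[SS, D1-]",8
Yamoussoukro,2016,"[RS, D1+]",15
Yamoussoukro,2016,"[RS, D1-]",15
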