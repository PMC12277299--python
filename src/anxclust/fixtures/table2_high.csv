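country,group,anxiety_pct,cluster
Cyprus,high,57,L-1
Lithuania,high,56,L-1
Bulgaria,high,55,L-1
Chile,high,55,L-1
Korea,high,55,L-1
Hungary,high,54,L-1
Estonia,high,53,L-1
Russia,high,52,L-1
Iceland,high,51,L-1
Austria,high,50,L-1
Finland,high,49,L-1
Croatia,high,47,L-2
France,high,47,L-2
Luxembourg,high,47,L-2
Slovak Republic,high,47,L-2
Poland,high,45,L-2
Israel,high,44,L-2
Latvia,high,43,L-2
Belgium,high,42,L-2
Germany,high,41,L-2
Czech Republic,high,40,L-2
Netherlands,high,39,L-2
Switzerland,high,33,L-2
Malaysia,high,82,H-1
Brazil,high,81,H-1
Costa Rica,high,81,H-1
Dominican Republic,high,80,H-1
Colombia,high,79,H-1
Singapore,high,76,H-1
Uruguay,high,73,H-1
Peru,high,72,H-1
New Zealand,high,72,H-1
United Kingdom,high,72,H-1
Portugal,high,69,H-2
Australia,high,67,H-2
Hong Kong (China),high,67,H-2
Spain,high,67,H-2
United States,high,67,H-2
Chinese Taipei,high,66,H-2
Macao (China),high,66,H-2
Denmark,high,65,H-2
Montenegro,high,65,H-2
Qatar,high,65,H-2
Canada,high,64,H-2
Ireland,high,63,H-2
Thailand,high,63,H-2
United Arab Emirates,high,63,H-2
China,high,62,H-2
Japan,high,62,H-2
Slovenia,high,62,H-2
Sweden,high,62,H-2
Norway,high,61,H-2
Greece,high,59,H-2
Mexico,high,59,H-2
Tunisia,high,59,H-2
Turkey,high,58,H-2
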